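"""Pollinator foraging observations: bouts, transitions, and summaries.

A *bout* is one pollinator's uninterrupted visit to a plot, from entry to
exit; a *transition* is a within-bout move between two plants.  Raw
observations arrive as one CSV row per plant visit; this module tallies
them into the inputs the ethological-isolation statistic and Bateman's
constancy index require.

Species labels follow a fixed two-species alphabet: ``A`` and ``B`` for the
parental species and ``H`` for hybrid-labelled plants.  Hybrid visits are
excluded from the two-species transition tally by default; a strict mode
rejects them outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from . import components
from .errors import SchemaError, UndefinedBarrierError, UndefinedIndexError

__all__ = [
    "Visit",
    "Bout",
    "TransitionTally",
    "tally_transitions",
    "classify_bouts",
    "visit_preference",
    "flowers_per_plant_summary",
    "ethological_summary",
    "PlotSummary",
    "read_bouts_csv",
    "write_bouts_csv",
]

SPECIES_LABELS = ("A", "B", "H")

BOUT_CSV_COLUMNS = [
    "bout_id",
    "pollinator_taxon",
    "plot_id",
    "visit_order",
    "plant_id",
    "species_label",
    "flowers_probed",
]


class Visit(NamedTuple):
    plant_id: str
    species_label: str
    flowers_probed: int


@dataclass(frozen=True)
class Bout:
    """One pollinator's ordered plant-visit sequence within a plot."""

    bout_id: str
    pollinator_taxon: str
    plot_id: str
    visits: tuple[Visit, ...]

    def __post_init__(self) -> None:
        if not self.visits:
            raise SchemaError(f"bout {self.bout_id!r} has no visits")
        for v in self.visits:
            if v.species_label not in SPECIES_LABELS:
                raise SchemaError(
                    f"bout {self.bout_id!r}: unknown species label "
                    f"{v.species_label!r} (expected one of {SPECIES_LABELS})"
                )

    @property
    def n_transitions(self) -> int:
        return len(self.visits) - 1

    @property
    def species_seen(self) -> frozenset[str]:
        return frozenset(v.species_label for v in self.visits)


@dataclass(frozen=True)
class TransitionTally:
    """Directed 2x2 plant-to-plant transition counts.

    First letter is the source species, second the destination; ``aa`` and
    ``bb`` are within-species moves, ``ab`` and ``ba`` heterospecific ones.
    """

    aa: int = 0
    ab: int = 0
    ba: int = 0
    bb: int = 0

    @property
    def total(self) -> int:
        return self.aa + self.ab + self.ba + self.bb

    @property
    def heterospecific(self) -> int:
        return self.ab + self.ba

    @property
    def conspecific(self) -> int:
        return self.aa + self.bb


def tally_transitions(
    bouts: Iterable[Bout], strict: bool = False
) -> TransitionTally:
    """Count consecutive plant pairs within bouts, never across bouts.

    Hybrid-labelled (``H``) visits are dropped from the tally; with
    ``strict`` their presence raises :class:`SchemaError`.  A move through
    a dropped visit does not create a transition between its neighbours.
    """
    counts = {"aa": 0, "ab": 0, "ba": 0, "bb": 0}
    for bout in bouts:
        prev: str | None = None
        for visit in bout.visits:
            label = visit.species_label
            if label == "H":
                if strict:
                    raise SchemaError(
                        f"bout {bout.bout_id!r} contains a hybrid-labelled "
                        "visit in strict two-species mode"
                    )
                prev = None
                continue
            if prev is not None:
                counts[prev.lower() + label.lower()] += 1
            prev = label
    return TransitionTally(**counts)


def classify_bouts(bouts: Sequence[Bout]) -> tuple[int, int]:
    """Split bouts into (conspecific, heterospecific) counts.

    A bout is heterospecific iff its visit sequence contains at least two
    distinct species labels; otherwise conspecific.
    """
    het = sum(1 for b in bouts if len(b.species_seen) >= 2)
    return len(bouts) - het, het


def visit_preference(bouts: Sequence[Bout], species: str) -> float:
    """Proportion of all plant visits made to ``species``."""
    total = sum(len(b.visits) for b in bouts)
    if total == 0:
        raise UndefinedBarrierError("no visits recorded")
    hits = sum(
        1 for b in bouts for v in b.visits if v.species_label == species
    )
    return hits / total


def flowers_per_plant_summary(
    bouts: Sequence[Bout], species: str, ddof: int = 1
) -> tuple[float, float]:
    """Mean and SD of flowers probed per plant visit to ``species``.

    ``ddof=1`` (sample SD) by default; the SD is 0 for a single visit.
    """
    values = [
        v.flowers_probed
        for b in bouts
        for v in b.visits
        if v.species_label == species
    ]
    if not values:
        raise UndefinedBarrierError(f"no visits to species {species!r}")
    n = len(values)
    mean = sum(values) / n
    if n <= ddof:
        return mean, 0.0
    var = sum((x - mean) ** 2 for x in values) / (n - ddof)
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class PlotSummary:
    """Ethological inputs and constancy index for one observation plot."""

    plot_id: str
    total_bouts: int
    heterospecific_bouts: int
    conspecific_bouts: int
    tally: TransitionTally
    ri_ethological: float
    bateman: float | None

    @property
    def ethological_inputs(self) -> tuple[int, int, int, int]:
        """(cross_bouts, total_bouts, het_transitions, total_transitions)."""
        return (
            self.heterospecific_bouts,
            self.total_bouts,
            self.tally.heterospecific,
            self.tally.total,
        )


def ethological_summary(bouts: Sequence[Bout]) -> PlotSummary:
    """Assemble ethological-RI inputs and Bateman's index for one plot."""
    plots = {b.plot_id for b in bouts}
    if len(plots) != 1:
        raise SchemaError(
            f"ethological_summary expects bouts from a single plot, "
            f"got {sorted(plots)!r}"
        )
    con, het = classify_bouts(bouts)
    tally = tally_transitions(bouts)
    ri = components.ri_ethological(het, len(bouts),
                                   tally.heterospecific, tally.total)
    try:
        bi = components.bateman_index(tally)
    except UndefinedIndexError:
        bi = None
    return PlotSummary(
        plot_id=plots.pop(),
        total_bouts=len(bouts),
        heterospecific_bouts=het,
        conspecific_bouts=con,
        tally=tally,
        ri_ethological=ri,
        bateman=bi,
    )


def read_bouts_csv(path: str | Path) -> list[Bout]:
    """Read the one-row-per-visit observation CSV into bouts.

    Strict header ``bout_id,pollinator_taxon,plot_id,visit_order,plant_id,
    species_label,flowers_probed``; visits are ordered by ``visit_order``
    within each bout.
    """
    df = pd.read_csv(path, dtype={"bout_id": str, "plant_id": str,
                                  "plot_id": str, "species_label": str})
    if list(df.columns) != BOUT_CSV_COLUMNS:
        raise SchemaError(
            f"bout CSV header must be {BOUT_CSV_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    bouts = []
    for bout_id, group in df.groupby("bout_id", sort=False):
        group = group.sort_values("visit_order")
        taxa = group["pollinator_taxon"].unique()
        plots = group["plot_id"].unique()
        if len(taxa) != 1 or len(plots) != 1:
            raise SchemaError(
                f"bout {bout_id!r} mixes pollinator taxa or plots"
            )
        visits = tuple(
            Visit(str(r.plant_id), str(r.species_label), int(r.flowers_probed))
            for r in group.itertuples()
        )
        bouts.append(
            Bout(str(bout_id), str(taxa[0]), str(plots[0]), visits)
        )
    return bouts


def write_bouts_csv(bouts: Iterable[Bout], path: str | Path) -> None:
    """Write bouts in the same one-row-per-visit CSV dialect."""
    rows = [
        {
            "bout_id": b.bout_id,
            "pollinator_taxon": b.pollinator_taxon,
            "plot_id": b.plot_id,
            "visit_order": i,
            "plant_id": v.plant_id,
            "species_label": v.species_label,
            "flowers_probed": v.flowers_probed,
        }
        for b in bouts
        for i, v in enumerate(b.visits)
    ]
    pd.DataFrame(rows, columns=BOUT_CSV_COLUMNS).to_csv(path, index=False)
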