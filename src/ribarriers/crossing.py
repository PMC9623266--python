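"""Hand-pollination outcomes: fruit set, seed set, postzygotic RI.

Each :class:`CrossRecord` is one pollination treatment applied to a batch
of emasculated, bagged flowers.  Postzygotic RI compares heterospecific
against conspecific performance on *rates*, not raw counts, so unequal
flower numbers across treatments are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .components import ri_postzygotic
from .errors import SchemaError, UndefinedBarrierError

__all__ = [
    "CrossRecord",
    "TREATMENTS",
    "fruit_set",
    "seeds_per_fruit",
    "PostzygoticRI",
    "postzygotic_components",
    "read_crossings_csv",
    "write_crossings_csv",
]

TREATMENTS = ("conspecific", "heterospecific", "geitonogamous", "xenogamous")


@dataclass(frozen=True)
class CrossRecord:
    """Outcome of one hand-pollination treatment."""

    maternal_species: str
    pollen_species: str
    treatment: str
    flowers_pollinated: int
    fruits: int
    seeds_total: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise SchemaError(
                f"treatment must be one of {TREATMENTS}, "
                f"got {self.treatment!r}"
            )
        if min(self.flowers_pollinated, self.fruits, self.seeds_total) < 0:
            raise SchemaError("counts must be non-negative")
        if self.fruits > self.flowers_pollinated:
            raise SchemaError(
                f"fruits ({self.fruits}) exceed flowers pollinated "
                f"({self.flowers_pollinated})"
            )


def fruit_set(r: CrossRecord) -> float:
    """Fruits per pollinated flower."""
    if r.flowers_pollinated == 0:
        raise UndefinedBarrierError("fruit set undefined: zero flowers")
    return r.fruits / r.flowers_pollinated


def seeds_per_fruit(r: CrossRecord, per: str = "fruit") -> float:
    """Seed yield, per fruit (default) or per pollinated flower.

    The per-flower variant folds fruit set into the seed rate and is the
    natural input to a seed-production barrier (total female fecundity per
    pollination); the per-fruit variant isolates seed development given
    fruit initiation.
    """
    if per == "fruit":
        if r.fruits == 0:
            raise UndefinedBarrierError("seeds per fruit undefined: no fruits")
        return r.seeds_total / r.fruits
    if per == "flower":
        if r.flowers_pollinated == 0:
            raise UndefinedBarrierError(
                "seeds per flower undefined: zero flowers"
            )
        return r.seeds_total / r.flowers_pollinated
    raise ValueError(f"per must be 'fruit' or 'flower', got {per!r}")


@dataclass(frozen=True)
class PostzygoticRI:
    """Fruit-set and seed-production RI for one maternal species."""

    ri_fruit: float
    ri_seed: float
    ri_fruit_raw: float
    ri_seed_raw: float


def postzygotic_components(
    conspecific: CrossRecord,
    heterospecific: CrossRecord,
    clip: bool = True,
    seed_per: str = "flower",
) -> PostzygoticRI:
    """Postzygotic RI pair from matched conspecific/heterospecific crosses.

    Fruit-set RI uses fruit-set rates; seed RI uses seed yield with the
    denominator chosen by ``seed_per`` (per-flower by default, see
    :func:`seeds_per_fruit`).  Raw values are preserved alongside the
    clipped ones (negative raw RI means heterospecific crosses
    outperformed conspecific ones).
    """
    if conspecific.maternal_species != heterospecific.maternal_species:
        raise SchemaError(
            "both records must share the maternal species; got "
            f"{conspecific.maternal_species!r} vs "
            f"{heterospecific.maternal_species!r}"
        )
    h_fruit = fruit_set(heterospecific)
    c_fruit = fruit_set(conspecific)
    h_seed = seeds_per_fruit(heterospecific, per=seed_per)
    c_seed = seeds_per_fruit(conspecific, per=seed_per)
    raw_fruit = ri_postzygotic(h_fruit, c_fruit, clip=False)
    raw_seed = ri_postzygotic(h_seed, c_seed, clip=False)
    return PostzygoticRI(
        ri_fruit=max(0.0, raw_fruit) if clip else raw_fruit,
        ri_seed=max(0.0, raw_seed) if clip else raw_seed,
        ri_fruit_raw=raw_fruit,
        ri_seed_raw=raw_seed,
    )


CROSSING_CSV_COLUMNS = [
    "maternal_species",
    "pollen_species",
    "treatment",
    "flowers_pollinated",
    "fruits",
    "seeds_total",
]


def read_crossings_csv(path: str | Path) -> list[CrossRecord]:
    """Read one-row-per-treatment crossing records."""
    df = pd.read_csv(path, dtype={"maternal_species": str,
                                  "pollen_species": str, "treatment": str})
    if list(df.columns) != CROSSING_CSV_COLUMNS:
        raise SchemaError(
            f"crossing CSV header must be {CROSSING_CSV_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return [
        CrossRecord(
            r.maternal_species,
            r.pollen_species,
            r.treatment,
            int(r.flowers_pollinated),
            int(r.fruits),
            int(r.seeds_total),
        )
        for r in df.itertuples()
    ]


def write_crossings_csv(
    records: Iterable[CrossRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "maternal_species": r.maternal_species,
                "pollen_species": r.pollen_species,
                "treatment": r.treatment,
                "flowers_pollinated": r.flowers_pollinated,
                "fruits": r.fruits,
                "seeds_total": r.seeds_total,
            }
            for r in records
        ],
        columns=CROSSING_CSV_COLUMNS,
    ).to_csv(path, index=False)
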