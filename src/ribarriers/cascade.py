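"""Sequential combination of barrier components into total RI.

Barriers act in life-history order: a stage can only block the gene flow
that earlier stages let through.  With component strengths ``v_1..v_k`` the
absolute contribution of stage ``n`` is

    AC_n = v_n * prod_{i<n} (1 - v_i)

total isolation is ``T = sum(AC_n) = 1 - prod(1 - v_i)``, and the relative
contribution of stage ``n`` is ``RC_n = AC_n / T``.

Prezygotic and postzygotic stages are cascaded separately in the standard
report (each life-history phase gets its own total), and a "sympatric"
scenario re-runs the prezygotic cascade with the geographic stage excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .components import BarrierComponent, round_half_up
from .errors import InvalidComponentError, SchemaError

__all__ = ["CascadeResult", "sequential_contributions", "build_table",
           "write_table_tsv", "format_table_text"]


@dataclass(frozen=True)
class CascadeResult:
    """Ordered barrier values with their sequential decomposition."""

    values: tuple[float, ...]
    absolute_contributions: tuple[float, ...]
    total: float
    relative_contributions: tuple[float, ...] | None
    scenario: str = ""

    @property
    def remaining_gene_flow(self) -> float:
        """Fraction of gene flow surviving every included stage."""
        return 1.0 - self.total


def sequential_contributions(
    values: Sequence[float | BarrierComponent], scenario: str = ""
) -> CascadeResult:
    """Decompose ordered barrier strengths into absolute contributions.

    Parameters
    ----------
    values
        Barrier strengths in life-history order, each in [0, 1].
        :class:`BarrierComponent` instances are accepted and contribute
        their (clipped) ``value``.
    scenario
        Free-text label carried through to the result (e.g.
        ``"allopatric"``).

    Returns
    -------
    CascadeResult
        With ``AC_n = v_n * prod_{i<n}(1 - v_i)``, ``T = sum(AC)`` and
        ``RC_n = AC_n / T`` (``None`` when ``T == 0``).
    """
    vals = [v.value if isinstance(v, BarrierComponent) else float(v)
            for v in values]
    if not vals:
        raise InvalidComponentError("component list must be non-empty")
    for v in vals:
        if not 0.0 <= v <= 1.0 or math.isnan(v):
            raise InvalidComponentError(
                f"component value must lie in [0, 1], got {v}"
            )
    acs: list[float] = []
    remaining = 1.0
    for v in vals:
        acs.append(v * remaining)
        remaining *= 1.0 - v
    total = sum(acs)
    rcs = tuple(ac / total for ac in acs) if total > 0 else None
    return CascadeResult(
        values=tuple(vals),
        absolute_contributions=tuple(acs),
        total=total,
        relative_contributions=rcs,
        scenario=scenario,
    )


_GEOGRAPHIC_NAMES = frozenset({"geographic", "geography"})


def _default_scenarios(
    components: Sequence[BarrierComponent],
) -> dict[str, list[bool]]:
    allopatric = [True] * len(components)
    sympatric = [c.stage_name.strip().lower() not in _GEOGRAPHIC_NAMES
                 for c in components]
    return {"allopatric": allopatric, "sympatric": sympatric}


def build_table(
    components_a: Sequence[BarrierComponent],
    components_b: Sequence[BarrierComponent],
    species: tuple[str, str] = ("species_A", "species_B"),
    scenarios: Mapping[str, Sequence[bool]] | None = None,
    round_digits: int = 4,
    sum_rounded: bool = False,
) -> pd.DataFrame:
    """Render the per-species barrier-contribution table.

    Both species must share the same ordered stage list.  Prezygotic and
    postzygotic stages are cascaded separately, each scenario mask selects
    which stages participate, and a ``Total`` row closes every stage class.

    Parameters
    ----------
    components_a, components_b
        Matched ordered :class:`BarrierComponent` lists for the two
        species.
    scenarios
        Mapping of scenario name to per-stage inclusion mask.  Default:
        ``allopatric`` (all stages) and ``sympatric`` (geographic stage
        excluded).
    sum_rounded
        If set, the ``Total`` rows sum the already-rounded absolute
        contributions, reproducing tables assembled from rounded cells;
        the default sums unrounded contributions and rounds once.
    """
    if [(c.stage_name, c.stage_class) for c in components_a] != [
        (c.stage_name, c.stage_class) for c in components_b
    ]:
        raise SchemaError("the two species' stage lists do not match")
    if scenarios is None:
        scenarios = _default_scenarios(components_a)
    for name, mask in scenarios.items():
        if len(mask) != len(components_a):
            raise SchemaError(
                f"scenario {name!r} mask length {len(mask)} != "
                f"{len(components_a)} stages"
            )

    per_species = {species[0]: components_a, species[1]: components_b}
    rows: list[dict] = []
    stage_classes = []
    for c in components_a:
        if c.stage_class not in stage_classes:
            stage_classes.append(c.stage_class)

    def _r(x: float) -> float:
        return round_half_up(x, round_digits)

    for stage_class in stage_classes:
        idx = [i for i, c in enumerate(components_a)
               if c.stage_class == stage_class]
        if not idx:
            continue
        class_rows = [
            {
                "barrier": components_a[i].stage_name,
                "stage_class": stage_class,
                **{f"component_{sp}": _r(per_species[sp][i].value)
                   for sp in species},
            }
            for i in idx
        ]
        totals: dict[str, float] = {}
        for scen, mask in scenarios.items():
            included = [i for i in idx if mask[i]]
            for sp in species:
                col = f"AC_{scen}_{sp}"
                if included:
                    res = sequential_contributions(
                        [per_species[sp][i].value for i in included],
                        scenario=scen,
                    )
                    acs = dict(zip(included, res.absolute_contributions))
                else:
                    acs = {}
                for row, i in zip(class_rows, idx):
                    row[col] = _r(acs[i]) if i in acs else float("nan")
                if sum_rounded:
                    totals[col] = _r(sum(_r(a) for a in acs.values()))
                else:
                    totals[col] = _r(sum(acs.values()))
        total_row = {"barrier": "Total", "stage_class": stage_class}
        for sp in species:
            total_row[f"component_{sp}"] = float("nan")
        total_row.update(totals)
        rows.extend(class_rows)
        rows.append(total_row)

    return pd.DataFrame(rows)


def write_table_tsv(table: pd.DataFrame, path) -> None:
    """Write the barrier table as tab-separated text."""
    table.to_csv(path, sep="\t", index=False, na_rep="")


def format_table_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the barrier table."""
    return table.to_string(index=False, na_rep="")
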