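"""Stage-specific reproductive-isolation (RI) statistics.

Each statistic quantifies how strongly one stage of the reproductive cycle
impedes inter-specific gene flow, on a 0 (no barrier) to 1 (complete
barrier) scale.  Two linear forms cover the barriers handled here:

* co-occurrence barriers (geography, phenology, pollinator assemblage)::

      RI = 1 - S / (S + U)

  where ``S`` is the shared amount of the factor (sympatric records,
  overlapping flowering days, visits by shared pollinator taxa) and ``U``
  the amount unique to the focal species;

* mating/fitness barriers (fruit set, seed production)::

      RI = 1 - 2 * H / (H + C)

  where ``H`` and ``C`` are the heterospecific and conspecific rates.  The
  raw value lies in [-1, 1]; a negative value means heterospecific crosses
  outperform conspecific ones, and the default policy clips it to 0 for
  reporting while preserving the raw value.

Ethological isolation from pollinator foraging multiplies the proportion of
cross-species foraging bouts by the proportion of heterospecific plant-to-
plant transitions; Bateman's constancy index summarises the same transition
table on a -1 (complete inconstancy) to +1 (complete constancy) scale.

All functions are pure, unit-agnostic (counts or proportions both work
because the formulas are scale-invariant), and raise
:class:`~ribarriers.errors.UndefinedBarrierError` on zero denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

from .errors import (
    InvalidCountError,
    UndefinedBarrierError,
    UndefinedIndexError,
)

__all__ = [
    "BarrierComponent",
    "ri_cooccurrence",
    "ri_pollinator_assemblage",
    "ri_ethological",
    "ri_postzygotic",
    "bateman_index",
    "round_half_up",
]

_STAGE_CLASSES = ("prezygotic", "postzygotic")


def round_half_up(x: float, digits: int = 4) -> float:
    """Round with ties away from zero, as barrier tables are printed.

    Uses decimal arithmetic on ``repr(x)`` so that values such as 0.99725
    round up to 0.9973 regardless of binary representation.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BarrierComponent:
    """One barrier stage's RI statistic.

    ``value_raw`` may be negative for postzygotic stages; ``value`` applies
    the clipping policy (``max(0, value_raw)`` by default) and is what the
    sequential cascade consumes.
    """

    stage_name: str
    stage_class: str
    value_raw: float
    clip: bool = True

    def __post_init__(self) -> None:
        if self.stage_class not in _STAGE_CLASSES:
            raise InvalidCountError(
                f"stage_class must be one of {_STAGE_CLASSES}, "
                f"got {self.stage_class!r}"
            )
        if not -1.0 <= self.value_raw <= 1.0:
            raise InvalidCountError(
                f"value_raw must lie in [-1, 1], got {self.value_raw}"
            )

    @property
    def value(self) -> float:
        """RI value after the clipping policy, guaranteed in [0, 1]."""
        if self.clip:
            return max(0.0, self.value_raw)
        return self.value_raw


def _check_nonnegative(**named: float) -> None:
    for name, v in named.items():
        if v < 0:
            raise InvalidCountError(f"{name} must be non-negative, got {v}")


def ri_cooccurrence(shared: float, unshared: float) -> float:
    """RI for a co-occurrence barrier: ``1 - S/(S+U)``.

    Parameters
    ----------
    shared
        Amount of the factor shared between the species (count or
        proportion), e.g. overlapping flowering days.
    unshared
        Amount unique to the focal species.
    """
    _check_nonnegative(shared=shared, unshared=unshared)
    total = shared + unshared
    if total == 0:
        raise UndefinedBarrierError(
            "co-occurrence RI undefined: shared + unshared == 0"
        )
    return 1.0 - shared / total


def ri_pollinator_assemblage(
    visit_counts_focal: Mapping[str, float],
    visit_counts_other: Mapping[str, float],
) -> float:
    """Pollinator-assemblage RI from per-taxon visit counts.

    A pollinator taxon is *shared* if it was observed visiting both plant
    species.  ``S`` is the number of focal-species visits made by shared
    taxa, ``U`` the number made by taxa unique to the focal species, and
    the statistic is ``ri_cooccurrence(S, U)``.
    """
    _check_nonnegative(
        **{f"focal[{k}]": v for k, v in visit_counts_focal.items()}
    )
    _check_nonnegative(
        **{f"other[{k}]": v for k, v in visit_counts_other.items()}
    )
    shared = 0.0
    unshared = 0.0
    for taxon, count in visit_counts_focal.items():
        if count == 0:
            continue
        if visit_counts_other.get(taxon, 0) > 0:
            shared += count
        else:
            unshared += count
    if shared + unshared == 0:
        raise UndefinedBarrierError(
            "pollinator-assemblage RI undefined: no focal visits"
        )
    return ri_cooccurrence(shared, unshared)


def ri_ethological(
    cross_bouts: float,
    total_bouts: float,
    het_transitions: float,
    total_transitions: float,
) -> float:
    """Ethological (pollinator-behaviour) RI.

    ``1 - (cross-species bouts / total bouts) *
    (heterospecific transitions / total transitions)``: the joint
    probability that a pollinator both enters a mixed foraging bout and
    actually moves between heterospecific plants.
    """
    _check_nonnegative(
        cross_bouts=cross_bouts,
        total_bouts=total_bouts,
        het_transitions=het_transitions,
        total_transitions=total_transitions,
    )
    if total_bouts == 0 or total_transitions == 0:
        raise UndefinedBarrierError(
            "ethological RI undefined: zero bouts or transitions"
        )
    if cross_bouts > total_bouts:
        raise InvalidCountError("cross_bouts exceeds total_bouts")
    if het_transitions > total_transitions:
        raise InvalidCountError("het_transitions exceeds total_transitions")
    return 1.0 - (cross_bouts / total_bouts) * (
        het_transitions / total_transitions
    )


def ri_postzygotic(
    heterospecific: float, conspecific: float, clip: bool = True
) -> float:
    """Postzygotic RI: ``1 - 2*H/(H+C)``.

    ``H`` and ``C`` are heterospecific and conspecific performance (fruit
    set, seeds per flower, ...).  The raw value is negative when
    heterospecific crosses outperform conspecific ones; with ``clip`` (the
    default) such values are reported as 0 (no barrier).
    """
    _check_nonnegative(heterospecific=heterospecific, conspecific=conspecific)
    total = heterospecific + conspecific
    if total == 0:
        raise UndefinedBarrierError(
            "postzygotic RI undefined: H + C == 0"
        )
    raw = 1.0 - 2.0 * heterospecific / total
    return max(0.0, raw) if clip else raw


def bateman_index(tally) -> float:
    """Bateman's floral-constancy index from a 2x2 transition table.

    ``(sqrt(aa*bb) - sqrt(ab*ba)) / (sqrt(aa*bb) + sqrt(ab*ba))`` where
    ``aa``/``bb`` count within-species transitions and ``ab``/``ba``
    heterospecific ones.  +1 means complete constancy, -1 complete
    inconstancy, 0 random foraging.

    ``tally`` may be any object with ``aa``, ``ab``, ``ba``, ``bb``
    attributes (e.g. :class:`ribarriers.pollinators.TransitionTally`) or a
    four-element sequence in that order.
    """
    if hasattr(tally, "aa"):
        aa, ab, ba, bb = tally.aa, tally.ab, tally.ba, tally.bb
    else:
        aa, ab, ba, bb = tally
    _check_nonnegative(aa=aa, ab=ab, ba=ba, bb=bb)
    same = math.sqrt(aa * bb)
    cross = math.sqrt(ab * ba)
    if same + cross == 0:
        raise UndefinedIndexError(
            "Bateman index undefined: aa*bb and ab*ba both zero"
        )
    return (same - cross) / (same + cross)
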