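"""Sequential-contribution cascade and barrier-table rendering."""

import math

import numpy as np
import pytest

from ribarriers import (
    BarrierComponent,
    build_table,
    round_half_up,
    sequential_contributions,
)
from ribarriers.errors import InvalidComponentError, SchemaError


def _r4(xs):
    return [round_half_up(x) for x in xs]


class TestSequentialContributions:
    def test_flava_allopatric(self):
        res = sequential_contributions([0.81, 0.13, 0, 0.9945])
        assert _r4(res.absolute_contributions) == [0.81, 0.0247, 0.0, 0.1644]
        assert round_half_up(res.total) == 0.9991

    def test_castanea_sympatric(self):
        res = sequential_contributions([0.26, 0.0183, 0.9973])
        assert _r4(res.absolute_contributions) == [0.26, 0.0135, 0.7245]

    def test_castanea_allopatric_assemblage(self):
        res = sequential_contributions([0.88, 0.26, 0.0183, 0.9973])
        assert round_half_up(res.absolute_contributions[2]) == 0.0016

    def test_complete_first_barrier_absorbs_everything(self):
        res = sequential_contributions([1.0, 0.5, 0.9])
        assert list(res.absolute_contributions) == [1.0, 0.0, 0.0]
        assert res.total == 1.0

    def test_relative_contributions_normalised(self):
        res = sequential_contributions([0.3, 0.4, 0.2])
        assert sum(res.relative_contributions) == pytest.approx(1.0)
        for ac, rc in zip(res.absolute_contributions,
                          res.relative_contributions):
            assert rc == pytest.approx(ac / res.total)

    def test_all_zero_components_leave_rc_undefined(self):
        res = sequential_contributions([0.0, 0.0])
        assert res.total == 0.0
        assert res.relative_contributions is None

    @pytest.mark.parametrize("bad", [[], [1.2], [-0.1], [float("nan")]])
    def test_invalid_components_rejected(self, bad):
        with pytest.raises(InvalidComponentError):
            sequential_contributions(bad)

    def test_accepts_barrier_components_and_clips(self):
        comps = [
            BarrierComponent("Fruit set", "postzygotic", -0.4),
            BarrierComponent("Seed production", "postzygotic", 0.0649),
        ]
        res = sequential_contributions(comps)
        assert res.values == (0.0, 0.0649)


class TestCascadeProperties:
    def test_product_identity(self):
        """T from summed ACs equals 1 - prod(1 - v) on random vectors."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            v = rng.random(rng.integers(1, 9))
            res = sequential_contributions(v)
            assert math.isclose(
                res.total, 1.0 - np.prod(1.0 - v), abs_tol=1e-12
            )
            assert math.isclose(
                sum(res.absolute_contributions), res.total, abs_tol=1e-12
            )

    def test_order_changes_acs_but_not_total(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = rng.uniform(0.05, 0.95, 5)
            perm = rng.permutation(5)
            a = sequential_contributions(v)
            b = sequential_contributions(v[perm])
            assert a.total == pytest.approx(b.total, abs=1e-12)
            assert not np.allclose(a.absolute_contributions,
                                   b.absolute_contributions) or np.allclose(
                v, v[perm])

    def test_adding_a_barrier_never_decreases_total(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            v = list(rng.random(4))
            extra = rng.uniform(0.01, 1.0)
            assert (sequential_contributions(v + [extra]).total
                    >= sequential_contributions(v).total)

    def test_ac_bounded_by_component(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            v = rng.random(6)
            res = sequential_contributions(v)
            for ac, vi in zip(res.absolute_contributions, v):
                assert 0.0 <= ac <= vi + 1e-15


class TestBuildTable:
    def test_study_table_cells(self, study):
        from ribarriers.datasets import CASTANEA, FLAVA

        table = build_table(study.components(FLAVA),
                            study.components(CASTANEA),
                            species=("flava", "castanea"))
        t = table.set_index(["barrier", "stage_class"])
        pre_total = t.loc[("Total", "prezygotic")]
        post_total = t.loc[("Total", "postzygotic")]
        assert pre_total["AC_allopatric_flava"] == 0.9991
        assert pre_total["AC_sympatric_castanea"] == 0.998
        assert post_total["AC_allopatric_flava"] == 0.0649
        assert post_total["AC_allopatric_castanea"] == 0.0585
        # published table assembled its castanea prezygotic total from
        # rounded cells; unrounded summation lands within 5e-4 of it
        assert pre_total["AC_allopatric_castanea"] == pytest.approx(
            0.9997, abs=5e-4
        )
        eth = t.loc[("Pollinator ethological", "prezygotic")]
        assert eth["AC_allopatric_flava"] == 0.1644
        assert eth["AC_allopatric_castanea"] == 0.0869
        assert eth["AC_sympatric_castanea"] == 0.7245
        # geographic stage excluded from the sympatric cascade
        geo = t.loc[("Geographic", "prezygotic")]
        assert math.isnan(geo["AC_sympatric_flava"])

    def test_sum_rounded_reproduces_cell_assembled_total(self, study):
        from ribarriers.datasets import CASTANEA, FLAVA

        table = build_table(study.components(FLAVA),
                            study.components(CASTANEA),
                            species=("flava", "castanea"), sum_rounded=True)
        t = table.set_index(["barrier", "stage_class"])
        assert t.loc[("Total", "prezygotic")]["AC_allopatric_castanea"] \
            == 0.9997

    def test_postzygotic_totals_standalone(self):
        a = [BarrierComponent("Fruit set", "postzygotic", 0.0),
             BarrierComponent("Seed production", "postzygotic", 0.0649)]
        b = [BarrierComponent("Fruit set", "postzygotic", 0.0244),
             BarrierComponent("Seed production", "postzygotic", 0.0350)]
        t = build_table(a, b).set_index("barrier")
        assert t.loc["Total"]["AC_allopatric_species_A"] == 0.0649
        assert t.loc["Total"]["AC_allopatric_species_B"] == 0.0585

    def test_empty_postzygotic_block_omitted(self):
        a = [BarrierComponent("Geographic", "prezygotic", 0.5)]
        b = [BarrierComponent("Geographic", "prezygotic", 0.6)]
        t = build_table(a, b)
        assert set(t["stage_class"]) == {"prezygotic"}

    def test_mismatched_stage_lists_rejected(self):
        a = [BarrierComponent("Geographic", "prezygotic", 0.5)]
        b = [BarrierComponent("Phenology", "prezygotic", 0.6)]
        with pytest.raises(SchemaError):
            build_table(a, b)
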