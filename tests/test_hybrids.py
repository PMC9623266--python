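"""Diagnostic-locus selection, FST, and genotype-class assignment."""

import numpy as np
import pytest

from ribarriers import (
    CLASSES,
    GenotypeTable,
    assign_class,
    assign_table,
    class_genotype_frequencies,
    per_locus_fst,
    select_diagnostic_loci,
)
from ribarriers.errors import EmptyPanelError, SchemaError, UndefinedFstError
from ribarriers.hybrids import (
    hudson_fst_ratio_of_sums,
    read_dosage_tsv,
    read_popmap,
    read_vcf,
    write_assignments_tsv,
)
from ribarriers.simulate import GenotypeConfig, simulate_genotypes, write_vcf


def _table(rows_a, rows_b, rows_u=(), loci=None):
    """Build a table from per-population dosage row lists."""
    dosages = [list(r) for r in (*rows_a, *rows_b, *rows_u)]
    n_loci = len(dosages[0])
    loci = loci or [f"L{j}" for j in range(n_loci)]
    individuals = (
        [f"a{i}" for i in range(len(rows_a))]
        + [f"b{i}" for i in range(len(rows_b))]
        + [f"u{i}" for i in range(len(rows_u))]
    )
    populations = (
        ["parentA"] * len(rows_a)
        + ["parentB"] * len(rows_b)
        + ["unknown"] * len(rows_u)
    )
    return GenotypeTable(individuals, populations, loci,
                         np.array(dosages, dtype=float))


class TestPerLocusFst:
    def test_fixed_difference_is_one(self):
        t = _table([[0], [0], [0]], [[2], [2], [2]])
        assert per_locus_fst(t, 0) == 1.0

    def test_identical_frequencies_clamp_to_zero(self):
        t = _table([[0], [1], [2]], [[0], [1], [2]])
        assert per_locus_fst(t, 0) == 0.0

    def test_matches_brute_force_estimator(self):
        # pA = 0.9, pB = 0.1 from 10 individuals each
        rows_a = [[2]] * 8 + [[1]] * 2
        rows_b = [[0]] * 8 + [[1]] * 2
        t = _table(rows_a, rows_b)
        p, q, na, nb = 0.9, 0.1, 20, 20
        expected = (
            (p - q) ** 2 - p * (1 - p) / (na - 1) - q * (1 - q) / (nb - 1)
        ) / (p * (1 - q) + q * (1 - p))
        assert per_locus_fst(t, 0) == pytest.approx(expected)

    def test_monomorphic_in_both_undefined(self):
        t = _table([[0], [0]], [[0], [0]])
        with pytest.raises(UndefinedFstError):
            per_locus_fst(t, 0)

    def test_all_missing_undefined(self):
        t = _table([[np.nan]], [[2]])
        with pytest.raises(UndefinedFstError):
            per_locus_fst(t, 0)

    def test_ratio_of_sums_multi_locus(self):
        t = _table([[0, 0], [0, 1]], [[2, 1], [2, 2]])
        combined = hudson_fst_ratio_of_sums(t)
        assert 0.0 <= combined <= 1.0
        # fixed locus alone gives 1; adding a polymorphic locus drags it down
        assert combined < 1.0


class TestDiagnosticSelection:
    def test_fixed_difference_loci_recovered_and_oriented(self):
        rows_a = [[0, 2, 1, 0], [0, 2, 1, 0]]
        rows_b = [[2, 0, 1, 0], [2, 0, 1, 0]]
        panel = select_diagnostic_loci(_table(rows_a, rows_b))
        assert panel.loci == ("L0", "L1")
        assert panel.orientation == (1, -1)

    def test_single_discordant_parental_genotype_excludes_locus(self):
        rows_a = [[0], [0], [1]]
        rows_b = [[2], [2], [2]]
        with pytest.raises(EmptyPanelError):
            select_diagnostic_loci(_table(rows_a, rows_b))

    def test_min_parental_n_gates_eligibility(self):
        rows_a = [[0], [np.nan], [np.nan]]
        rows_b = [[2], [2], [2]]
        t = _table(rows_a, rows_b)
        assert len(select_diagnostic_loci(t, min_parental_n=1)) == 1
        with pytest.raises(EmptyPanelError):
            select_diagnostic_loci(t, min_parental_n=2)

    def test_simulated_panels_recovered_exactly(self):
        cfg = GenotypeConfig(
            n_per_class={}, n_ref=20, n_diagnostic=40, n_filler=160,
            error_rate=0.0, missing_rate=0.0, ref_error_rate=0.0,
        )
        table, _, truth = simulate_genotypes(cfg, seed=17)
        panel = select_diagnostic_loci(table, min_parental_n=10)
        assert set(panel.loci) == set(truth.loci)
        for locus in panel.loci:
            assert per_locus_fst(table, locus) == 1.0

    def test_oriented_dosages_count_parent_b_alleles(self):
        rows_a = [[2, 0]] * 2
        rows_b = [[0, 2]] * 2
        t = _table(rows_a, rows_b, rows_u=[[2, 0]])
        panel = select_diagnostic_loci(t)
        oriented = panel.oriented_dosages(t)
        # the unknown matches parent A at both loci -> 0 parent-B alleles
        assert oriented[-1].tolist() == [0.0, 0.0]


class TestClassFrequencies:
    @pytest.mark.parametrize(
        "cls, expected",
        [
            ("P1", (1, 0, 0)), ("P2", (0, 0, 1)), ("F1", (0, 1, 0)),
            ("F2", (0.25, 0.5, 0.25)), ("BC1", (0.5, 0.5, 0)),
            ("BC2", (0, 0.5, 0.5)),
        ],
    )
    def test_mendelian_expectations(self, cls, expected):
        f = class_genotype_frequencies(cls)
        assert tuple(f) == expected
        assert f.sum() == 1.0

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            class_genotype_frequencies("F3")


class TestAssignClass:
    def test_all_heterozygous_is_f1_not_f2(self):
        a = assign_class([1.0] * 80, error_rate=0.01)
        assert a.best_class == "F1"
        assert a.posteriors["F1"] > 0.999
        # direct arithmetic: per locus F1 likelihood 0.99 vs F2 0.4975
        expected_ratio = ((0.99) / (0.4975)) ** 80
        assert a.posteriors["F1"] / a.posteriors["F2"] == pytest.approx(
            expected_ratio, rel=1e-6
        )
        assert a.interclass_heterozygosity == 1.0

    def test_pure_parent(self):
        a = assign_class([0.0] * 40)
        assert a.best_class == "P1"
        assert a.hybrid_index == 0.0

    def test_posteriors_sum_to_one_and_best_attains_max(self):
        rng = np.random.default_rng(5)
        g = rng.choice([0.0, 1.0, 2.0, np.nan], size=60,
                       p=[0.3, 0.3, 0.3, 0.1])
        a = assign_class(g)
        assert sum(a.posteriors.values()) == pytest.approx(1.0, abs=1e-9)
        assert a.posteriors[a.best_class] == max(a.posteriors.values())

    def test_locus_order_irrelevant(self):
        rng = np.random.default_rng(8)
        g = rng.choice([0.0, 1.0, 2.0], size=50, p=[0.25, 0.5, 0.25])
        a = assign_class(g)
        b = assign_class(g[rng.permutation(50)])
        for cls in CLASSES:
            assert a.posteriors[cls] == pytest.approx(b.posteriors[cls])

    def test_parent_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        g = rng.choice([0.0, 1.0, 2.0], size=50, p=[0.4, 0.4, 0.2])
        a = assign_class(g)
        b = assign_class(2.0 - g)
        swap = {"P1": "P2", "P2": "P1", "BC1": "BC2", "BC2": "BC1",
                "F1": "F1", "F2": "F2"}
        for cls in CLASSES:
            assert a.posteriors[cls] == pytest.approx(b.posteriors[swap[cls]])
        assert a.hybrid_index == pytest.approx(1.0 - b.hybrid_index)

    def test_missing_loci_skipped_and_no_call_flagged(self):
        g = [1.0, np.nan, 1.0, np.nan]
        a = assign_class(g)
        assert a.n_loci_used == 2
        no_call = assign_class([np.nan] * 5)
        assert not no_call.called and no_call.best_class is None

    def test_zero_prior_class_excluded(self):
        prior = {c: 1.0 for c in CLASSES}
        prior["F1"] = 0.0
        a = assign_class([1.0] * 80, prior=prior)
        assert a.posteriors["F1"] == 0.0
        assert a.best_class == "F2"

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            assign_class([1.0], error_rate=0.5)


class TestSimulatedRecovery:
    def test_class_recovery_on_simulated_individuals(self):
        """>= 95 % correct over 600 simulated individuals, no F1/F2 mixups."""
        cfg = GenotypeConfig(
            n_per_class={c: 100 for c in CLASSES}, n_ref=20,
            n_diagnostic=80, n_filler=0,
            error_rate=0.01, missing_rate=0.05,
        )
        table, truth, _ = simulate_genotypes(cfg, seed=20)
        panel = select_diagnostic_loci(table, min_parental_n=10)
        assignments = assign_table(table, panel=panel, error_rate=0.01)
        correct = sum(
            1 for a in assignments if a.best_class == truth[a.individual]
        )
        assert correct / len(assignments) >= 0.95
        for a in assignments:
            if truth[a.individual] in ("F1", "F2"):
                assert a.best_class not in (
                    {"F1", "F2"} - {truth[a.individual]}
                )

    def test_f1_f2_heterozygosity_separation(self):
        cfg = GenotypeConfig(
            n_per_class={"F1": 60, "F2": 60}, n_ref=10, n_diagnostic=80,
            n_filler=0, error_rate=0.0, missing_rate=0.0,
        )
        table, truth, _ = simulate_genotypes(cfg, seed=21)
        assignments = assign_table(table, error_rate=0.01)
        f2_het = []
        f2_hi = []
        for a in assignments:
            if truth[a.individual] == "F1":
                assert a.interclass_heterozygosity == 1.0
            else:
                f2_het.append(a.interclass_heterozygosity)
                f2_hi.append(a.hybrid_index)
        # per-locus heterozygosity is Bernoulli(1/2): the mean over 60
        # individuals x 80 loci sits within 3 SE of 0.5, and no single
        # individual strays far enough to be confused with F1 or BC
        se_ind = (0.25 / 80) ** 0.5
        se_mean = se_ind / len(f2_het) ** 0.5
        assert abs(np.mean(f2_het) - 0.5) < 3 * se_mean
        assert abs(np.mean(f2_hi) - 0.5) < 3 * se_mean
        assert max(abs(h - 0.5) for h in f2_het) < 5 * se_ind


class TestIO:
    def test_popmap_and_dosage_tsv(self, tmp_path):
        pop = tmp_path / "popmap.tsv"
        pop.write_text("a1\tparentA\nb1\tparentB\nu1\tunknown\n")
        popmap = read_popmap(pop)
        tsv = tmp_path / "dos.tsv"
        tsv.write_text(
            "individual\tL1\tL2\na1\t0\t0\nb1\t2\t2\nu1\t1\tNA\n"
        )
        t = read_dosage_tsv(tsv, popmap)
        assert t.individuals == ["a1", "b1", "u1"]
        assert np.isnan(t.dosages[2, 1])
        panel = select_diagnostic_loci(t)
        assert panel.loci == ("L1", "L2")

    def test_bad_popmap_label_rejected(self, tmp_path):
        pop = tmp_path / "popmap.tsv"
        pop.write_text("a1\thybridzone\n")
        with pytest.raises(SchemaError):
            read_popmap(pop)

    def test_vcf_round_trip_matches_dosages(self, tmp_path):
        cfg = GenotypeConfig(
            n_per_class={"F2": 5}, n_ref=3, n_diagnostic=6, n_filler=4,
            error_rate=0.0, missing_rate=0.2,
        )
        table, _, _ = simulate_genotypes(cfg, seed=2)
        vcf_path = tmp_path / "sim.vcf"
        write_vcf(table, vcf_path)
        popmap = dict(zip(table.individuals, table.populations))
        back = read_vcf(vcf_path, popmap)
        assert back.individuals == table.individuals
        assert back.loci == table.loci
        np.testing.assert_array_equal(back.dosages, table.dosages)

    def test_assignment_tsv_written(self, tmp_path):
        a = assign_class([1.0] * 10, individual="u1")
        out = tmp_path / "assign.tsv"
        write_assignments_tsv([a], out)
        text = out.read_text()
        assert "u1" in text and "P_F1" in text

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            GenotypeTable(["a"], ["parentA"], ["L1", "L2"],
                          np.zeros((1, 1)))
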