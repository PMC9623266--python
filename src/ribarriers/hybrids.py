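"""Diagnostic-locus selection and hybrid genotype-class assignment.

Given allele-dosage genotypes for two parental reference samples plus
individuals of unknown ancestry, this module

1. selects *diagnostic loci* — loci at which the two parental samples are
   fixed for alternative alleles (per-locus FST = 1), so that every allele
   copy identifies its parental origin — and orients them so dosage 2
   always means two parent-B alleles; and
2. assigns each unknown individual to one of the six canonical early-
   generation classes (P1, P2, F1, F2, BC1, BC2) by a per-individual
   posterior over the classes' expected diagnostic genotype frequencies,
   with a symmetric genotyping-error rate and missing genotypes skipped.

Expected genotype frequencies (P(dosage = 0, 1, 2) of the parent-B allele)
follow Mendelian expectation at unlinked diagnostic loci:

    P1 (1, 0, 0)    P2 (0, 0, 1)    F1 (0, 1, 0)
    F2 (1/4, 1/2, 1/4)    BC1 (1/2, 1/2, 0)    BC2 (0, 1/2, 1/2)

The assignment is a direct independent-loci posterior, not an MCMC
sampler: with a fixed diagnostic panel the likelihood factorises exactly,
so no sampling is needed and results are deterministic.  Two classical
summaries accompany each call: the hybrid index (fraction of diagnostic
alleles of parent-B origin) and interclass heterozygosity (fraction of
diagnostic loci heterozygous; expectation 1.0 for F1, 0.5 for F2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyPanelError, SchemaError, UndefinedFstError

__all__ = [
    "CLASSES",
    "GenotypeTable",
    "DiagnosticPanel",
    "ClassAssignment",
    "per_locus_fst",
    "hudson_fst_ratio_of_sums",
    "select_diagnostic_loci",
    "class_genotype_frequencies",
    "assign_class",
    "assign_table",
    "read_dosage_tsv",
    "read_popmap",
    "read_vcf",
    "write_assignments_tsv",
]

CLASSES = ("P1", "P2", "F1", "F2", "BC1", "BC2")

_CLASS_FREQS: dict[str, np.ndarray] = {
    "P1": np.array([1.0, 0.0, 0.0]),
    "P2": np.array([0.0, 0.0, 1.0]),
    "F1": np.array([0.0, 1.0, 0.0]),
    "F2": np.array([0.25, 0.5, 0.25]),
    "BC1": np.array([0.5, 0.5, 0.0]),
    "BC2": np.array([0.0, 0.5, 0.5]),
}

POPULATION_LABELS = ("parentA", "parentB", "unknown")

# per-locus likelihood floor; keeps log-space sums finite if a caller
# insists on error_rate == 0 and a discordant genotype appears
_LIKELIHOOD_FLOOR = 1e-15


@dataclass
class GenotypeTable:
    """Individuals x loci allele-dosage matrix with population labels.

    ``dosages`` counts copies of a designated reference allele (0/1/2),
    with ``NaN`` for missing calls.  ``populations`` labels each individual
    ``parentA``, ``parentB`` or ``unknown``.  Loci are assumed unlinked.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individuals) or m != len(self.loci):
            raise SchemaError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(self.populations) != n:
            raise SchemaError("population labels do not match individuals")
        bad = set(self.populations) - set(POPULATION_LABELS)
        if bad:
            raise SchemaError(
                f"unknown population labels {sorted(bad)}; "
                f"expected {POPULATION_LABELS}"
            )
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            raise SchemaError("dosages must be 0, 1, 2 or missing")

    def _pop_rows(self, label: str) -> np.ndarray:
        return np.array([p == label for p in self.populations])

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _parental_freq(
    table: GenotypeTable, locus_idx: int, label: str
) -> tuple[float, int]:
    """Reference-allele frequency and sampled allele count in one population."""
    col = table.dosages[table._pop_rows(label), locus_idx]
    col = col[~np.isnan(col)]
    n_alleles = 2 * col.size
    if n_alleles == 0:
        return np.nan, 0
    return float(col.sum()) / n_alleles, n_alleles


def per_locus_fst(table: GenotypeTable, locus: str | int) -> float:
    """Hudson's FST estimator between the two parental samples at a locus.

    With reference-allele frequencies ``p`` and ``q`` estimated from
    ``nA`` and ``nB`` sampled allele copies::

        ((p-q)^2 - p(1-p)/(nA-1) - q(1-q)/(nB-1)) / (p(1-q) + q(1-p))

    clamped to [0, 1].  Equals 1 iff the two samples are fixed for
    alternative alleles.  Raises :class:`UndefinedFstError` when either
    sample has no calls or both samples are fixed for the same allele
    (zero between-population heterozygosity).
    """
    idx = table.loci.index(locus) if isinstance(locus, str) else locus
    p, na = _parental_freq(table, idx, "parentA")
    q, nb = _parental_freq(table, idx, "parentB")
    if na == 0 or nb == 0:
        raise UndefinedFstError(
            f"locus {table.loci[idx]!r}: no parental calls"
        )
    denom = p * (1 - q) + q * (1 - p)
    if denom == 0:
        raise UndefinedFstError(
            f"locus {table.loci[idx]!r}: monomorphic for the same allele "
            "in both parental samples"
        )
    num = (p - q) ** 2
    if na > 1:
        num -= p * (1 - p) / (na - 1)
    if nb > 1:
        num -= q * (1 - q) / (nb - 1)
    return float(np.clip(num / denom, 0.0, 1.0))


def hudson_fst_ratio_of_sums(
    table: GenotypeTable, loci: Sequence[str | int] | None = None
) -> float:
    """Multi-locus Hudson FST averaged as a ratio of sums.

    Sums the per-locus numerators and denominators before dividing, the
    recommended way to combine loci (per-locus ratios are noisy at small
    counts).  Loci with undefined per-locus terms are skipped.
    """
    if loci is None:
        loci = list(range(table.n_loci))
    num_sum = 0.0
    den_sum = 0.0
    used = 0
    for locus in loci:
        idx = table.loci.index(locus) if isinstance(locus, str) else locus
        p, na = _parental_freq(table, idx, "parentA")
        q, nb = _parental_freq(table, idx, "parentB")
        if na == 0 or nb == 0:
            continue
        denom = p * (1 - q) + q * (1 - p)
        num = (p - q) ** 2
        if na > 1:
            num -= p * (1 - p) / (na - 1)
        if nb > 1:
            num -= q * (1 - q) / (nb - 1)
        num_sum += num
        den_sum += denom
        used += 1
    if used == 0 or den_sum == 0:
        raise UndefinedFstError("no locus with a defined FST term")
    return float(np.clip(num_sum / den_sum, 0.0, 1.0))


@dataclass(frozen=True)
class DiagnosticPanel:
    """Oriented diagnostic-locus subset of a genotype table.

    ``orientation`` is +1 where the reference allele is the parent-A
    allele (oriented dosage = raw dosage counts parent-B alleles) and -1
    where it must be flipped (oriented dosage = 2 - raw).
    """

    loci: tuple[str, ...]
    indices: tuple[int, ...]
    orientation: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.loci)

    def oriented_dosages(self, table: GenotypeTable) -> np.ndarray:
        """Individuals x panel matrix of parent-B allele counts."""
        sub = table.dosages[:, list(self.indices)].copy()
        flip = np.array(self.orientation) == -1
        sub[:, flip] = 2.0 - sub[:, flip]
        return sub


def select_diagnostic_loci(
    table: GenotypeTable, min_parental_n: int = 1
) -> DiagnosticPanel:
    """Select loci fixed for alternative alleles in the parental samples.

    A locus is eligible when each parental population has at least
    ``min_parental_n`` called genotypes there, and diagnostic when every
    called parent-A genotype is one homozygote and every called parent-B
    genotype the opposite homozygote (per-locus FST = 1).  The returned
    panel is oriented so dosage 2 always means two parent-B alleles.
    """
    rows_a = table._pop_rows("parentA")
    rows_b = table._pop_rows("parentB")
    if not rows_a.any() or not rows_b.any():
        raise SchemaError("both parental populations must be present")
    loci: list[str] = []
    indices: list[int] = []
    orientation: list[int] = []
    for j in range(table.n_loci):
        a = table.dosages[rows_a, j]
        b = table.dosages[rows_b, j]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < min_parental_n or b.size < min_parental_n:
            continue
        if (a == 0).all() and (b == 2).all():
            sign = +1
        elif (a == 2).all() and (b == 0).all():
            sign = -1
        else:
            continue
        loci.append(table.loci[j])
        indices.append(j)
        orientation.append(sign)
    if not loci:
        raise EmptyPanelError(
            "no diagnostic loci found (no locus fixed for alternative "
            "alleles in the parental samples); class assignment cannot run"
        )
    return DiagnosticPanel(tuple(loci), tuple(indices), tuple(orientation))


def class_genotype_frequencies(cls: str) -> np.ndarray:
    """Expected (f0, f1, f2) diagnostic genotype frequencies for a class."""
    try:
        return _CLASS_FREQS[cls].copy()
    except KeyError:
        raise ValueError(
            f"unknown genotype class {cls!r}; expected one of {CLASSES}"
        ) from None


@dataclass(frozen=True)
class ClassAssignment:
    """Posterior class membership of one individual."""

    individual: str
    posteriors: dict[str, float]
    best_class: str | None
    n_loci_used: int
    hybrid_index: float | None
    interclass_heterozygosity: float | None

    @property
    def called(self) -> bool:
        return self.best_class is not None


def assign_class(
    dosages: Sequence[float] | np.ndarray,
    error_rate: float = 0.01,
    prior: Mapping[str, float] | None = None,
    individual: str = "",
) -> ClassAssignment:
    """Posterior genotype-class assignment over an oriented diagnostic panel.

    Parameters
    ----------
    dosages
        Parent-B allele counts (0/1/2, ``NaN`` for missing) at the
        diagnostic loci, already oriented.
    error_rate
        Symmetric per-genotype error probability ``eps`` in [0, 0.5): an
        observed genotype is correct with probability ``1 - eps`` and each
        of the two wrong genotypes with probability ``eps / 2``, so the
        per-locus likelihood is ``(1-eps) * f_g + eps * (1 - f_g) / 2``.
    prior
        Class prior; uniform over the six classes by default.

    Missing loci are skipped; with no called loci a flagged no-call
    result is returned (``best_class is None``).
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError(f"error_rate must lie in [0, 0.5), got {error_rate}")
    g = np.asarray(dosages, dtype=float)
    called = ~np.isnan(g)
    n_used = int(called.sum())
    if n_used == 0:
        return ClassAssignment(individual, {c: np.nan for c in CLASSES},
                               None, 0, None, None)
    g_called = g[called].astype(int)
    if prior is None:
        prior = {c: 1.0 for c in CLASSES}
    finite: dict[str, float] = {}
    for cls in CLASSES:
        if prior.get(cls, 0.0) <= 0:
            continue  # zero-prior classes drop out entirely
        f = class_genotype_frequencies(cls)
        per_genotype = (1.0 - error_rate) * f + error_rate * (1.0 - f) / 2.0
        lik = np.maximum(per_genotype[g_called], _LIKELIHOOD_FLOOR)
        finite[cls] = float(np.log(prior[cls]) + np.log(lik).sum())
    if not finite:
        raise ValueError("prior assigns zero mass to every class")
    m = max(finite.values())
    unnorm = {c: np.exp(lp - m) for c, lp in finite.items()}
    z = sum(unnorm.values())
    posteriors = {c: unnorm.get(c, 0.0) / z for c in CLASSES}
    best = max(posteriors, key=posteriors.get)
    return ClassAssignment(
        individual=individual,
        posteriors=posteriors,
        best_class=best,
        n_loci_used=n_used,
        hybrid_index=float(g_called.sum()) / (2 * n_used),
        interclass_heterozygosity=float((g_called == 1).sum()) / n_used,
    )


def assign_table(
    table: GenotypeTable,
    panel: DiagnosticPanel | None = None,
    error_rate: float = 0.01,
    prior: Mapping[str, float] | None = None,
    min_parental_n: int = 1,
    include_parents: bool = False,
) -> list[ClassAssignment]:
    """Assign every ``unknown`` individual (optionally parents too)."""
    if panel is None:
        panel = select_diagnostic_loci(table, min_parental_n=min_parental_n)
    oriented = panel.oriented_dosages(table)
    out = []
    for i, (ind, pop) in enumerate(zip(table.individuals, table.populations)):
        if pop != "unknown" and not include_parents:
            continue
        out.append(
            assign_class(oriented[i], error_rate=error_rate, prior=prior,
                         individual=ind)
        )
    return out


# ---------------------------------------------------------------------------
# I/O

def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column individual/label TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise SchemaError("population map must have exactly two columns")
    popmap = dict(zip(df[0], df[1]))
    bad = set(popmap.values()) - set(POPULATION_LABELS)
    if bad:
        raise SchemaError(
            f"population map labels {sorted(bad)} not in {POPULATION_LABELS}"
        )
    return popmap


def _labels_for(individuals: Sequence[str],
                popmap: Mapping[str, str]) -> list[str]:
    missing = [i for i in individuals if i not in popmap]
    if missing:
        raise SchemaError(
            f"individuals missing from population map: {missing[:5]}"
        )
    return [popmap[i] for i in individuals]


def read_dosage_tsv(path: str | Path,
                    popmap: Mapping[str, str]) -> GenotypeTable:
    """Read a TSV dosage matrix (rows = individuals, columns = loci).

    Values 0/1/2 with ``NA`` (or blank) for missing; first column holds
    individual identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeTable(
        individuals=[str(i) for i in df.index],
        populations=_labels_for([str(i) for i in df.index], popmap),
        loci=[str(c) for c in df.columns],
        dosages=df.to_numpy(dtype=float),
    )


def read_vcf(path: str | Path, popmap: Mapping[str, str]) -> GenotypeTable:
    """Read diploid GT fields from a VCF into a dosage table.

    Only biallelic sites are used; dosage counts copies of the ALT allele.
    Phased and unphased genotypes are both accepted; any genotype with a
    missing allele becomes a missing call.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        loci.append(name)
        rows.append(dos)
    vcf.close()
    dosages = (np.column_stack(rows) if rows
               else np.empty((len(individuals), 0)))
    return GenotypeTable(
        individuals=individuals,
        populations=_labels_for(individuals, popmap),
        loci=loci,
        dosages=dosages,
    )


def write_assignments_tsv(
    assignments: Iterable[ClassAssignment], path: str | Path
) -> None:
    """Write one row per individual with posteriors and summaries."""
    rows = []
    for a in assignments:
        row = {"individual": a.individual, "best_class": a.best_class or "NA",
               "n_loci_used": a.n_loci_used,
               "hybrid_index": a.hybrid_index,
               "interclass_heterozygosity": a.interclass_heterozygosity}
        for c in CLASSES:
            row[f"P_{c}"] = a.posteriors.get(c, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
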