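"""Synthetic field and genotype data with known ground truth.

Every input the pipeline consumes can be generated here with controllable
truth, so all stages are testable without field work or sequencing:

* pollinator foraging bouts in a mixed plot with a tunable floral-
  constancy parameter ``c`` (``c = 1`` pure constancy, ``c = 0``
  composition-random foraging);
* diagnostic-locus genotypes drawn from the six canonical hybrid classes'
  Mendelian genotype frequencies, with symmetric genotyping error and
  missingness, plus shared-polymorphism filler loci;
* hand-pollination outcomes with binomial fruit set and truncated-Poisson
  seed counts (truncated at 4: the study genus sets at most four seeds —
  one per ovule — per flower);
* clustered spatial occurrences with a planted sympatric fraction; and
* species flowering seasons.

Defaults mirror the conditions of the motivating field study of the
*Salvia flava* x *S. castanea* hybrid zone (plot composition 6 + 6 plants,
~130 bouts, 80 diagnostic loci, 35 flowers per crossing treatment,
36 + 58 occurrence records with roughly one in six focal records
sympatric, flowering late July to mid October).

All generators take a :class:`numpy.random.Generator` or integer seed and
are deterministic given the seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .crossing import CrossRecord
from .hybrids import CLASSES, GenotypeTable, class_genotype_frequencies
from .phenogeo import FlowerSeason, OccurrenceRecord
from .pollinators import Bout, Visit

__all__ = [
    "BoutConfig",
    "GenotypeConfig",
    "CrossingConfig",
    "OccurrenceConfig",
    "SeasonConfig",
    "SimulationConfig",
    "simulate_bouts",
    "simulate_genotypes",
    "simulate_crossings",
    "simulate_occurrences",
    "simulate_seasons",
    "write_vcf",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# configs

@dataclass
class BoutConfig:
    """Foraging-bout generator settings.

    ``constancy`` interpolates between composition-random foraging (0) and
    perfect constancy (1): after the first visit, a pollinator stays on
    the current species with probability ``c + (1 - c) * w_same`` where
    ``w_same`` is that species' share of plot plants, else moves to a
    plant of another species with probability proportional to composition.
    """

    n_bouts: int = 129
    n_plants: Mapping[str, int] = field(
        default_factory=lambda: {"A": 6, "B": 6}
    )
    constancy: float = 0.9
    mean_visits: float = 2.6
    mean_flowers: float = 2.4
    plot_id: str = "plot-1"
    pollinator_taxa: Mapping[str, float] = field(
        default_factory=lambda: {"honeybee": 0.9, "bumblebee": 0.1}
    )


@dataclass
class GenotypeConfig:
    """Diagnostic-genotype generator settings."""

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 100 for c in CLASSES}
    )
    n_ref: int = 20
    n_diagnostic: int = 80
    n_filler: int = 120
    error_rate: float = 0.01
    missing_rate: float = 0.05
    ref_error_rate: float = 0.0


@dataclass
class CrossingTreatment:
    maternal_species: str
    pollen_species: str
    treatment: str
    flowers: int
    p_fruit: float
    mean_seeds_per_fruit: float


def _default_treatments() -> list[CrossingTreatment]:
    # parental fruit-set probabilities follow the published heterospecific
    # rates (0.80 toward flava mothers, 0.5714 toward castanea mothers) and
    # plausible conspecific rates; hybrid selfing rates are the published
    # 48.57 % / 42.86 %
    return [
        CrossingTreatment("flava", "flava", "conspecific", 35, 0.70, 2.0),
        CrossingTreatment("flava", "castanea", "heterospecific", 35, 0.80, 1.8),
        CrossingTreatment("castanea", "castanea", "conspecific", 35, 0.60, 2.0),
        CrossingTreatment("castanea", "flava", "heterospecific", 35, 0.5714, 1.8),
        CrossingTreatment("hybrid", "hybrid", "geitonogamous", 35, 0.4857, 1.9),
        CrossingTreatment("hybrid", "hybrid", "xenogamous", 35, 0.4286, 2.2),
    ]


@dataclass
class CrossingConfig:
    treatments: list[CrossingTreatment] = field(
        default_factory=_default_treatments
    )
    max_seeds_per_fruit: int = 4


@dataclass
class OccurrenceConfig:
    """Clustered occurrences with a planted sympatric fraction.

    ``sympatric_fraction`` of the focal records are placed within
    ``sympatry_radius_km`` of a heterospecific record; the remainder is
    drawn around a focal cluster centre far enough away that no stray
    sympatry can occur, so ``ri_geographic`` equals
    ``1 - round(f * n) / n`` exactly by construction.
    """

    focal_species: str = "flava"
    other_species: str = "castanea"
    n_focal: int = 36
    n_other: int = 58
    sympatric_fraction: float = 6 / 36
    focal_center: tuple[float, float] = (27.4, 100.4)
    other_center: tuple[float, float] = (30.0, 95.0)
    dispersion_km: float = 10.0
    sympatry_radius_km: float = 7.0
    elevation_mean: Mapping[str, float] = field(
        default_factory=lambda: {"flava": 3400.0, "castanea": 3100.0}
    )
    elevation_sd: float = 350.0


@dataclass
class SeasonConfig:
    seasons: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "flava": ("2019-07-20", "2019-09-25"),
            "castanea": ("2019-08-01", "2019-10-15"),
        }
    )


@dataclass
class SimulationConfig:
    """Seed plus one block per generator; loadable from YAML or JSON."""

    seed: int = 0
    bouts: BoutConfig = field(default_factory=BoutConfig)
    genotypes: GenotypeConfig = field(default_factory=GenotypeConfig)
    crossings: CrossingConfig = field(default_factory=CrossingConfig)
    occurrences: OccurrenceConfig = field(default_factory=OccurrenceConfig)
    seasons: SeasonConfig = field(default_factory=SeasonConfig)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs: dict = {"seed": int(data.get("seed", 0))}
        if "bouts" in data:
            kwargs["bouts"] = BoutConfig(**data["bouts"])
        if "genotypes" in data:
            kwargs["genotypes"] = GenotypeConfig(**data["genotypes"])
        if "crossings" in data:
            block = dict(data["crossings"])
            if "treatments" in block:
                block["treatments"] = [
                    CrossingTreatment(**t) for t in block["treatments"]
                ]
            kwargs["crossings"] = CrossingConfig(**block)
        if "occurrences" in data:
            block = dict(data["occurrences"])
            for key in ("focal_center", "other_center"):
                if key in block:
                    block[key] = tuple(block[key])
            kwargs["occurrences"] = OccurrenceConfig(**block)
        if "seasons" in data:
            kwargs["seasons"] = SeasonConfig(
                seasons={k: tuple(v) for k, v in data["seasons"].items()}
            )
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML superset also parses JSON
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# generators

def simulate_bouts(cfg: BoutConfig, seed=0) -> list[Bout]:
    """Draw foraging bouts in a mixed plot under constancy ``c``."""
    rng = _rng(seed)
    species = [s for s, n in cfg.n_plants.items() if n > 0]
    if not species:
        raise ValueError("plot has no plants")
    weights = np.array([cfg.n_plants[s] for s in species], dtype=float)
    weights /= weights.sum()
    plants = {
        s: [f"{s}{i + 1}" for i in range(cfg.n_plants[s])] for s in species
    }
    taxa = list(cfg.pollinator_taxa)
    taxa_w = np.array([cfg.pollinator_taxa[t] for t in taxa], dtype=float)
    taxa_w /= taxa_w.sum()
    c = cfg.constancy

    bouts = []
    for b in range(cfg.n_bouts):
        taxon = taxa[rng.choice(len(taxa), p=taxa_w)]
        n_visits = 1 + rng.poisson(max(cfg.mean_visits - 1, 0.0))
        sp = species[rng.choice(len(species), p=weights)]
        plant = plants[sp][rng.integers(len(plants[sp]))]
        visits = []
        for _ in range(n_visits):
            flowers = 1 + rng.poisson(max(cfg.mean_flowers - 1, 0.0))
            visits.append(Visit(plant, sp, int(flowers)))
            # choose next plant
            i_sp = species.index(sp)
            p_stay = c + (1 - c) * weights[i_sp]
            if len(species) == 1 or rng.random() < p_stay:
                next_sp = sp
            else:
                others = [s for s in species if s != sp]
                w = np.array([cfg.n_plants[s] for s in others], dtype=float)
                w /= w.sum()
                next_sp = others[rng.choice(len(others), p=w)]
            pool = [p for p in plants[next_sp] if p != plant]
            if not pool:
                pool = plants[next_sp]
            plant = pool[rng.integers(len(pool))]
            sp = next_sp
        bouts.append(
            Bout(f"bout{b + 1}", taxon, cfg.plot_id, tuple(visits))
        )
    return bouts


def _apply_error(dosages: np.ndarray, eps: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Replace each genotype with one of the two others with prob eps."""
    if eps <= 0:
        return dosages
    flip = rng.random(dosages.shape) < eps
    if not flip.any():
        return dosages
    out = dosages.copy()
    wrong_choice = rng.integers(0, 2, size=dosages.shape)
    for g in (0, 1, 2):
        others = [x for x in (0, 1, 2) if x != g]
        mask = flip & (dosages == g)
        out[mask] = np.where(wrong_choice[mask] == 0, others[0], others[1])
    return out


def simulate_genotypes(
    cfg: GenotypeConfig, seed=0
) -> tuple[GenotypeTable, dict[str, str], DiagnosticTruth]:
    """Draw a genotype table with known true classes.

    Returns the table, a mapping individual -> true class for the
    ``unknown`` individuals, and the ground-truth diagnostic panel (the
    first ``n_diagnostic`` loci, all oriented with parent B as the ALT
    homozygote).  Parental reference individuals are generated with
    ``ref_error_rate`` (0 by default, emulating a curated reference
    panel); unknowns with ``error_rate``.  Missingness applies to all.
    """
    rng = _rng(seed)
    n_diag, n_fill = cfg.n_diagnostic, cfg.n_filler
    loci = [f"diag{j + 1}" for j in range(n_diag)] + [
        f"fill{j + 1}" for j in range(n_fill)
    ]

    individuals: list[str] = []
    populations: list[str] = []
    truth: dict[str, str] = {}
    blocks: list[np.ndarray] = []

    def _draw_class_block(cls: str, n: int, eps: float) -> np.ndarray:
        f = class_genotype_frequencies(cls)
        diag = rng.choice(3, size=(n, n_diag), p=f).astype(float)
        diag = _apply_error(diag, eps, rng)
        return diag

    # parental references
    for label, cls in (("parentA", "P1"), ("parentB", "P2")):
        diag = _draw_class_block(cls, cfg.n_ref, cfg.ref_error_rate)
        blocks.append(diag)
        for i in range(cfg.n_ref):
            individuals.append(f"{label}_{i + 1}")
            populations.append(label)

    # unknowns, per true class
    for cls in CLASSES:
        n = cfg.n_per_class.get(cls, 0)
        if n == 0:
            continue
        diag = _draw_class_block(cls, n, cfg.error_rate)
        blocks.append(diag)
        for i in range(n):
            name = f"{cls}_{i + 1}"
            individuals.append(name)
            populations.append("unknown")
            truth[name] = cls

    diag_all = np.vstack(blocks) if blocks else np.empty((0, n_diag))
    n_ind = diag_all.shape[0]

    # shared-polymorphism filler loci: same allele frequency in everyone
    if n_fill:
        p = rng.uniform(0.2, 0.8, size=n_fill)
        fill = rng.binomial(2, p[None, :], size=(n_ind, n_fill)).astype(float)
        dosages = np.hstack([diag_all, fill])
    else:
        dosages = diag_all

    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan

    table = GenotypeTable(individuals, populations, loci, dosages)
    panel_truth = DiagnosticTruth(
        loci=tuple(loci[:n_diag]), orientation=tuple([1] * n_diag)
    )
    return table, truth, panel_truth


@dataclass(frozen=True)
class DiagnosticTruth:
    """Ground-truth diagnostic loci planted by the simulator."""

    loci: tuple[str, ...]
    orientation: tuple[int, ...]


def simulate_crossings(cfg: CrossingConfig, seed=0) -> list[CrossRecord]:
    """Binomial fruit set, truncated-Poisson seeds per fruit."""
    rng = _rng(seed)
    records = []
    for t in cfg.treatments:
        fruits = int(rng.binomial(t.flowers, t.p_fruit))
        seeds = int(
            np.minimum(
                rng.poisson(t.mean_seeds_per_fruit, size=fruits),
                cfg.max_seeds_per_fruit,
            ).sum()
        ) if fruits else 0
        records.append(
            CrossRecord(
                t.maternal_species,
                t.pollen_species,
                t.treatment,
                t.flowers,
                fruits,
                seeds,
            )
        )
    return records


_KM_PER_DEG_LAT = 111.19492664455873  # 6371 km * pi / 180


def _jitter(center: tuple[float, float], km: float,
            n: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian scatter on the local tangent plane, returned as lat/lon."""
    lat0, lon0 = center
    dy = rng.normal(0, km, n) / _KM_PER_DEG_LAT
    dx = rng.normal(0, km, n) / (
        _KM_PER_DEG_LAT * np.cos(np.radians(lat0))
    )
    return np.column_stack([lat0 + dy, lon0 + dx])


def simulate_occurrences(
    cfg: OccurrenceConfig, seed=0
) -> tuple[list[OccurrenceRecord], int]:
    """Occurrence records with a planted number of sympatric focal points.

    Returns the records (both species) and the exact number of sympatric
    focal records planted, so ``ri_geographic`` has a known truth of
    ``1 - planted / n_focal``.
    """
    rng = _rng(seed)
    other_pts = _jitter(cfg.other_center, cfg.dispersion_km,
                        cfg.n_other, rng)
    n_sym = int(round(cfg.sympatric_fraction * cfg.n_focal))
    n_allo = cfg.n_focal - n_sym
    allo_pts = _jitter(cfg.focal_center, cfg.dispersion_km, n_allo, rng)
    # sympatric focal points: offset < radius/2 from a random other-record
    sym_rows = rng.integers(0, cfg.n_other, size=n_sym)
    offsets_km = rng.uniform(0, cfg.sympatry_radius_km / 2, size=n_sym)
    angles = rng.uniform(0, 2 * np.pi, size=n_sym)
    sym_pts = other_pts[sym_rows].copy()
    sym_pts[:, 0] += offsets_km * np.sin(angles) / _KM_PER_DEG_LAT
    sym_pts[:, 1] += (
        offsets_km * np.cos(angles)
        / (_KM_PER_DEG_LAT * np.cos(np.radians(cfg.other_center[0])))
    )

    def _elev(species: str, n: int) -> np.ndarray:
        mean = cfg.elevation_mean.get(species, 3000.0)
        return np.clip(rng.normal(mean, cfg.elevation_sd, n), 0, None)

    records = []
    focal_pts = np.vstack([allo_pts, sym_pts]) if cfg.n_focal else allo_pts
    for pts, species, elevs in (
        (focal_pts, cfg.focal_species, _elev(cfg.focal_species, cfg.n_focal)),
        (other_pts, cfg.other_species, _elev(cfg.other_species, cfg.n_other)),
    ):
        for (lat, lon), e in zip(pts, elevs):
            records.append(
                OccurrenceRecord(species, float(lat), float(lon), float(e))
            )
    return records, n_sym


def simulate_seasons(cfg: SeasonConfig) -> dict[str, FlowerSeason]:
    """Materialise configured flowering intervals."""
    return {
        sp: FlowerSeason(
            sp, dt.date.fromisoformat(a), dt.date.fromisoformat(b)
        )
        for sp, (a, b) in cfg.seasons.items()
    }


# ---------------------------------------------------------------------------
# VCF emission (GT-only sites file for the classifier's VCF reader)

def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write the dosage table as a minimal diploid GT-only VCF.

    Loci become biallelic A/T sites on one synthetic contig, dosage
    counting ALT copies; missing calls become ``./.``.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=sim1,length={len(table.loci) + 1}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        for j, locus in enumerate(table.loci):
            calls = [
                gt_map.get(table.dosages[i, j], "./.")
                if not np.isnan(table.dosages[i, j])
                else "./."
                for i in range(table.n_individuals)
            ]
            fh.write(
                f"sim1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
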