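# Methods

## Barrier statistics

Each barrier stage is scored on a 0–1 scale (0 = no barrier, 1 = complete
barrier to inter-specific gene flow). Two linear forms cover all stages:

* **Co-occurrence barriers** (geography, phenology, pollinator
  assemblage): `RI = 1 − S/(S+U)`, with `S` the shared amount of the
  factor and `U` the amount unique to the focal species. The statistic is
  scale-invariant, so counts and proportions are interchangeable.
* **Postzygotic barriers** (fruit set, seed production):
  `RI = 1 − 2H/(H+C)` on the heterospecific (`H`) and conspecific (`C`)
  rates. The raw value lies in [−1, 1]; negative values mean
  heterospecific crosses outperform conspecific ones. The default policy
  clips reported values at 0 while preserving the raw value, because a
  "negative barrier" has no meaning in the sequential cascade; the
  `clip=False` switch exposes the raw asymmetry.

Stage-specific conventions:

* **Geographic**: a focal occurrence record is *sympatric* when at least
  one heterospecific record lies within 7 km (inclusive), a conventional
  pollen/seed-dispersal horizon for bee-pollinated montane herbs;
  `RI = allopatric fraction`. Distances are spherical haversine with
  R = 6371 km — the ellipsoidal correction is far below the 7-km threshold
  granularity. De-duplication of repeated collections is the caller's
  decision; `duplicate_coordinates` flags exact matches.
* **Phenology**: `S` = flowering-overlap days, `S+U` = the focal species'
  season length, both counted inclusive of endpoints. Inclusive counting
  is the only convention that reproduces both the 56-day overlap and the
  *S. castanea* value (0.26) in the bundled dataset. Seasons spanning a
  year boundary are rejected rather than guessed at.
* **Pollinator assemblage**: `S` = focal-species visits by pollinator taxa
  observed on both plant species, `U` = visits by taxa unique to the focal
  species. This grouping reproduces both bundled values (0 and 0.0183)
  from the raw visit counts; taxa recorded with zero visits are ignored.
* **Ethological**: `RI = 1 − (cross-species bouts/total bouts) ×
  (heterospecific transitions/total transitions)` — the joint probability
  that a pollinator both enters a mixed bout and actually moves between
  heterospecific plants. A *bout* is one pollinator's plot visit from
  entry to exit; a bout is heterospecific iff its visit sequence contains
  ≥ 2 distinct species labels (this is the only definition under which
  bout and transition counts stay mutually consistent). Single-visit bouts
  count as bouts but contribute no transitions. Hybrid-labelled plants are
  excluded from the two-species transition tally (a strict mode rejects
  them), and a move through an excluded plant does not bridge its
  neighbours. Transition direction is preserved (ab ≠ ba) even though
  published totals pool them.
* **Bateman's constancy index**
  `BI = (√(aa·bb) − √(ab·ba)) / (√(aa·bb) + √(ab·ba))` ranges from −1
  (complete inconstancy) through 0 (random foraging) to +1 (complete
  constancy) and is undefined when both products are zero.

## Sequential cascade

Barriers act in life-history order; stage *n* can only remove the gene
flow earlier stages let through:

    AC_n = v_n · Π_{i<n}(1 − v_i),  T = Σ AC_n = 1 − Π(1 − v_i),  RC_n = AC_n / T

`T` is order-invariant, the ACs are not. Prezygotic and postzygotic stages
are cascaded separately — each life-history phase gets its own total, as
barrier tables in this literature report them — and an optional combined
cascade is a one-liner on the concatenated values. The *sympatric*
scenario re-runs the prezygotic cascade with the geographic stage
excluded.

Rounding: values are carried unrounded through the cascade and rounded
half-up (decimal arithmetic, 4 digits by default) only for display. Totals
sum unrounded ACs by default; the `sum_rounded` switch instead sums the
rounded cells, for compatibility with tables assembled cell-by-cell (the
bundled study's *S. castanea* allopatric prezygotic total, 0.9997, is such
a cell; unrounded summation gives 0.9998, and tests accept that cell to
±0.0005).

## Hybrid classification

The six early-generation classes have exact Mendelian genotype-frequency
expectations at unlinked diagnostic loci (probabilities of carrying 0/1/2
parent-B alleles):

| class | f0 | f1 | f2 |
|-------|----|----|----|
| P1 | 1 | 0 | 0 |
| P2 | 0 | 0 | 1 |
| F1 | 0 | 1 | 0 |
| F2 | ¼ | ½ | ¼ |
| BC1 | ½ | ½ | 0 |
| BC2 | 0 | ½ | ½ |

*Diagnostic loci* are selected where the two parental reference samples
are fixed for alternative alleles — equivalently, per-locus Hudson F_ST
(the `(p−q)²`-based estimator with finite-sample correction, clamped to
[0, 1]) equals 1 — subject to a minimum number of called parental
genotypes per population (`min_parental_n`, default 1; raise it for small
or gappy reference panels). The panel is oriented so dosage 2 always means
two parent-B alleles. Multi-locus F_ST summaries use the same estimator
combined as a ratio of sums.

Assignment is a direct per-individual posterior: per-locus likelihood
`(1−ε)·f_g + ε·(1−f_g)/2` (a symmetric error model spreading the
genotyping-error rate ε equally over the two wrong genotypes), accumulated
in log space across loci, times a class prior (uniform by default).
Missing loci are skipped; an all-missing individual yields a flagged
no-call. Because the diagnostic panel is fixed and loci are independent,
the likelihood factorises exactly and no MCMC is needed: results are
deterministic, and label symmetry (swapping the parents swaps P1↔P2 and
BC1↔BC2 and maps the hybrid index h → 1−h) holds to machine precision.
ε defaults to 0.01; with ε = 0 a single discordant genotype would zero a
class, so a per-locus likelihood floor (1e−15) keeps log-sums finite.
Reported alongside the posterior: the hybrid index (Σ dosages / 2·n
called) and interclass heterozygosity (fraction of called diagnostic loci
heterozygous; expectation 1.0 for F1, 0.5 for F2 — the pair that separates
those two otherwise admixture-identical classes).

With 80 diagnostic loci, ε = 0.01 and 5 % missingness — the scale of the
motivating study's smaller SNP panel — simulated individuals recover their
true class ≥ 95 % of the time and F1/F2 are never confused; residual
errors are P↔BC and BC↔F2 boundary cases, as expected from the
frequency table.

## Synthetic data

Generators emulate every pipeline input with planted truth. Defaults are
the motivating study's conditions; where a quantity was not published, a
single field-realistic choice is fixed here.

* **Bouts**: plot of 6 + 6 plants; bout length 1 + Poisson(mean − 1)
  visits (default mean 2.6 visits, matching ≈ 203 transitions per 129
  bouts); flowers probed per plant 1 + Poisson(mean − 1) (default mean
  2.4, inside the published 2.0–3.0 per-species range). After the first
  visit (drawn by plot composition) the pollinator stays on the current
  species with probability `c + (1−c)·w_same`, else switches
  composition-proportionally, so `c = 1` gives pure constancy and `c = 0`
  composition-random foraging. Default `c = 0.9` (strong constancy, as
  observed). `c` is the simulator's knob, related to but not identical to
  BI — tests assert monotonicity, not equality.
* **Genotypes**: parental reference panels (default 20 per parent, drawn
  error-free as a curated reference; configurable) plus unknowns drawn
  from their true class's frequency table with error ε and missingness;
  filler loci carry a polymorphism shared by everyone (allele frequency
  uniform on [0.2, 0.8]) and are never diagnostic.
* **Crossings**: fruits ~ Binomial(flowers, p); seeds per fruit ~
  Poisson truncated at 4 (the genus sets at most four seeds — one per
  ovule — per flower). Default treatment probabilities use the published
  rates where printed (heterospecific fruit set 0.80 / 0.5714; hybrid
  selfing 0.4857 / 0.4286) and plausible conspecific rates (0.70 / 0.60)
  where only supplementary material reports them.
* **Occurrences**: Gaussian clusters (σ = 10 km) on the local tangent
  plane around per-species centres placed far apart; a planted fraction of
  focal records is dropped within half the sympatry radius of a
  heterospecific record, so geographic RI is `1 − round(f·n)/n` exactly.
  Default 36 + 58 records with f = 1/6 (RI ≈ 0.83).
* **Seasons**: the two study intervals (Jul 20–Sep 25, Aug 1–Oct 15).

All generators are deterministic given an integer seed, and every output
round-trips through the corresponding reader's schema validation. What
passing simulation tests do **not** show: real foraging has temporal and
spatial autocorrelation beyond a single stay-probability, real diagnostic
panels are ascertained from noisy parental samples rather than planted,
and real occurrence data carry spatially structured collection bias —
conclusions about those effects need real data.

## Bundled study dataset and documented discrepancies

`ribarriers.datasets.salvia_field_study()` carries the printed counts and
component values of the motivating hybrid-zone study so the barrier table
is reproducible offline. Three source inconsistencies are handled
explicitly rather than silently:

1. The study text reports the plot-1 transition split as "five
   conspecific / 65 heterospecific", which contradicts the plot's own
   ethological RI (0.9945) and constancy index; the bundled data store 5
   heterospecific / 65 conspecific, the only reading consistent with both.
2. The *S. flava* phenology component (0.13) is not derivable from the
   printed flowering dates — inclusive counting gives 0.1765, and no
   simple day-count convention yields 0.13. The published 0.13 is carried
   as an override for the cascade; the date-derived value is what
   `ri_phenology` returns.
3. The *S. flava* geographic RI appears as 0.83 in the study text and 0.81
   in its barrier table; the bundled components use the table value, and
   the text value is retained as `GEOGRAPHIC_RI_TEXT`.

The bundled per-species BI values (0.8447 / 0.8411) cannot be recomputed
because the underlying aa/ab/ba/bb split was not printed; BI is therefore
validated by simulator properties (monotonicity in `c`, exact ±1/0
endpoints), not by table matching. Likewise the diagnostic-SNP counts of
the study's two locations (80 / 379) derive from raw sequencing data and
are out of reach of a desk reproduction; the classifier is validated on
simulated data with planted truth.

## Numerical and interface choices

* Inputs are validated at the boundary (strict CSV headers, dosage
  alphabet {0, 1, 2, NA}, coordinate and date ranges); violations raise
  typed exceptions (`SchemaError`, `UndefinedBarrierError`, ...) rather
  than propagating NaNs.
* Zero denominators are *undefined*, not 0 or 1: `S + U = 0`,
  `H + C = 0`, zero bouts/transitions and all-zero transition products
  all raise.
* VCF input is parsed with cyvcf2 (diploid GT only, biallelic sites,
  phased or unphased); the synthetic generator emits a minimal GT-only
  VCFv4.2 text file that round-trips through that reader.
* Seed-production RI takes seeds-per-flower by default (total female
  fecundity per pollination, folding fruit initiation and seed development
  into one rate); `seed_per="fruit"` isolates seed development instead.
  The published hybrid seed numbers (0.9429, 1.0286 with n = 35 flowers)
  behave like per-flower means, which motivated the default.
* Problem sizes in the test suite (600 simulated individuals × 80 loci for
  classifier recovery, 4,500 bouts ≥ 10,000 transitions per constancy
  grid point, 1,000 random vectors for the cascade identity) were chosen
  to hold sampling error well below the asserted tolerances while keeping
  the whole suite in seconds.

## Known limitations

* The cascade assumes barriers act independently and in a fixed order;
  reordering changes the ACs (by design) and correlated barriers are not
  modelled.
* The classifier covers only the six early-generation classes: later
  generations (F3+, double backcrosses) are absent from the hypothesis
  space and will be absorbed mostly into F2/BC, and linkage between
  diagnostic loci would overstate posterior confidence.
* No significance testing or confidence intervals on RI components —
  the package computes the descriptive statistics the study design calls
  for and leaves inference to general-purpose tools.
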