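# ribarriers

Stage-specific **reproductive-isolation (RI) barrier analysis** for plant
hybrid zones: barrier-strength statistics, pollinator-behaviour indices, a
sequential absolute/relative-contribution cascade, and a diagnostic-locus
classifier that assigns putative hybrids to the six canonical
early-generation genotype classes.

It is written for field botanists and population geneticists studying pairs
of co-occurring, hybridizing plant species — the motivating system is the
hybrid zone between the alpine sages *Salvia flava* and *S. castanea* on
the Qinghai-Tibet Plateau, whose published observation counts ship with the
package — but every statistic is a pure function of ordinary field inputs
(occurrence records, flowering dates, pollinator visit logs,
hand-pollination outcomes, SNP genotypes).

## The statistics

For barriers that act through co-occurrence (geography, phenology,
pollinator assemblage), with *S* the shared amount of the factor and *U*
the amount unique to the focal species:

    RI = 1 − S / (S + U)

For postzygotic barriers, with *H* and *C* the heterospecific and
conspecific performance rates (fruit set, seed yield):

    RI = 1 − 2H / (H + C)        (negative values clipped to 0 by default)

Ethological isolation from pollinator foraging:

    RI = 1 − (cross-species bouts / total bouts) × (heterospecific transitions / total transitions)

Bateman's floral-constancy index from the 2×2 transition table
(aa, ab, ba, bb):

    BI = (√(aa·bb) − √(ab·ba)) / (√(aa·bb) + √(ab·ba))

Ordered barriers v₁…vₖ combine sequentially: the absolute contribution of
stage *n* is ACₙ = vₙ · Π_{i<n}(1 − vᵢ), total isolation is
T = Σ ACₙ = 1 − Π(1 − vᵢ), and the relative contribution is RCₙ = ACₙ/T.

Hybrid classification selects *diagnostic loci* (fixed for alternative
alleles in the two parental samples, per-locus Hudson F_ST = 1) and
computes each individual's posterior over {P1, P2, F1, F2, BC1, BC2} from
Mendelian genotype-frequency expectations with a symmetric genotyping-error
rate, plus the hybrid index and interclass heterozygosity.

## Worked example

The bundled field-study dataset reproduces the published barrier table:

```sh
ribarriers ri-table --dataset study
```

prints (abridged):

```
               barrier stage_class  component_S. flava  component_S. castanea  AC_allopatric_S. flava  AC_allopatric_S. castanea  AC_sympatric_S. flava  AC_sympatric_S. castanea
            Geographic  prezygotic              0.8100                 0.8800                  0.8100                     0.8800
             Phenology  prezygotic              0.1300                 0.2600                  0.0247                     0.0312                 0.1300                    0.2600
 Pollinator assemblage  prezygotic              0.0000                 0.0183                  0.0000                     0.0016                 0.0000                    0.0135
Pollinator ethological  prezygotic              0.9945                 0.9973                  0.1644                     0.0869                 0.8652                    0.7245
                 Total  prezygotic                                                            0.9991                     0.9998                 0.9952                    0.9980
             Fruit set postzygotic              0.0000                 0.0244                  0.0000                     0.0244                 0.0000                    0.0244
       Seed production postzygotic              0.0649                 0.0350                  0.0649                     0.0341                 0.0649                    0.0341
                 Total postzygotic                                                            0.0649                     0.0585                 0.0649                    0.0585
```

Reading: prezygotic isolation is nearly complete for both species
(T ≈ 0.999 with geography included, ≈ 0.995–0.998 for sympatric plants,
where pollinator behaviour alone contributes 0.72–0.87), while postzygotic
isolation is weak (≤ 0.065) — hybridization is limited almost entirely by
barriers acting before fertilization.  The pollinator components in the
table are recomputed from the bundled raw visit and transition counts; the
`--sum-rounded` flag reproduces totals assembled from rounded cells
(0.9997 for the *S. castanea* allopatric prezygotic column).

The same statistics are available as plain functions:

```python
>>> from ribarriers import ri_ethological, sequential_contributions
>>> round(ri_ethological(4, 52, 5, 70), 4)          # plot-level counts
0.9945
>>> res = sequential_contributions([0.81, 0.13, 0, 0.9945])
>>> [round(a, 4) for a in res.absolute_contributions]
[0.81, 0.0247, 0.0, 0.1644]
>>> round(res.total, 4)
0.9991
```

A full synthetic workflow (simulate every input with known ground truth,
then analyse it):

```sh
ribarriers simulate --seed 3 --out sim/
ribarriers behavior  --bouts sim/bouts.csv
ribarriers classify  --genotypes sim/genotypes.vcf --popmap sim/popmap.tsv --out sim/assignments.tsv
```

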