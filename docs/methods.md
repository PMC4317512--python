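# Methods

## Genetic model

Each line is represented by two phased haplotypes over a fixed panel of
biallelic loci, every allele labelled by parental origin (`A` = Avalon,
`C` = Cadenza). Parents and doubled haploids (DH) are fully homozygous by
construction. Meiosis uses the Haldane mapping model: crossovers are a
Poisson process along the chromosome, so the recombination fraction between
loci `d` cM apart is `r = (1 − e^(−2d/100))/2` and gametes are first-order
Markov mosaics of the two haplotypes (switch probability `r` between
adjacent loci, a fair haplotype draw at each chromosome start). No
crossover interference is modelled; Haldane is the standard closed-form
choice for breeding-program simulators and makes the per-interval switch
probabilities independent.

Phenotypes are purely additive. An effect entry is a triple (trait,
environment, additive effect) plus the parental origin of the increasing
allele; a homozygote contributes `±a`, a heterozygote `0` (no dominance —
only additive effects enter the model, and all selected material is
homozygous at the loci that matter). Pleiotropy is a locus with several
trait entries; the increasing origin is stored per entry because co-located
effects can favour opposite parents (e.g. the 3B locus where the
solid-stem-increasing allele reduces height). Predictions are relative
genotypic values: the baseline defaults to 0 (the midparent of an
all-heterozygous genotype) because absolute parental environment means are
not part of the packaged data.

## Study fixture and provenance

The packaged fixture reproduces the published 23-locus selection panel:
genotypes of the five DH parents (DH27, DH61, DH182, DH109, DH160), the
Avalon/Cadenza origin patterns, and the designed target genotype, which
mixes alleles from both parents (transgressive). Internal integrity checks
assert full parental homozygosity and the published segregating-locus
counts of the three crosses — 13 (DH61×DH182), 15 (DH27×DH61) and
16 (DH109×DH160).

Every additive-effect row carries a provenance flag:

* `paper` — published magnitudes: 0.37 t/ha (2D yield, Cadenza), 0.21 t/ha
  (2A yield, Avalon), 4.92 cm (2D height, Cadenza), 4.42 cm (3A height,
  taken as the lower end of the published 4.42–4.92 cm range for the major
  height loci), 2.4 cm (3B height, Avalon), 20.29 % straw fill (3B solid
  stem, Cadenza), 1.72 g (5A thousand-grain weight, Cadenza), 0.15 cm
  (5A grain length, Cadenza), 856.47 g/m² (2D grain number, Cadenza).
* `synthetic` — package-chosen stand-ins at field-realistic magnitudes for
  effects whose values were never published (the minor yield loci at 0.20
  and 0.15 t/ha, minor height loci at 2.0–2.5 cm, ear-emergence loci at
  1.0–3.0 % of mean, the 4D height effect at 4.67 cm inside the published
  range). Directions follow the published narrative (e.g. Avalon tall at
  2A, Cadenza-early flowering at 5A, Avalon-early at 6A).

Resistance genes, root QTL and *Vrn-A1b* carry no effect rows — their
magnitudes were never published — and participate in marker-assisted
selection only.

**Map positions are package defaults, not measured values.** Chromosome
assignments follow the locus names and published gene locations (*Yr6* →
7B, *Yr7* → 2B, *Sbm1* → 5D, *Vrn-A1* → 5A). cM spacings are not published,
so they were fixed once by exact enumeration (F1 gamete distribution → F2
pair distribution conditional on enrichment → DH / four-generation selfing
chain per chromosome group) such that the co-located 5A group — which sits
in repulsion phase relative to the target in all three crosses — exerts a
drag on target counts of the magnitude the study observed, while enrichment
retention stays near its free-recombination expectation. The defaults place
the six 5A panel loci at 0/60/65/130/200/260 cM with *Vrn-A1b* distal at
370 cM, the 3A loci 110 cM apart, the 2A loci 110 cM apart, the 3B loci
60 cM apart and the 6A loci 75 cM apart. All positions are configurable
through the TSV map interface.

## Strategies

All strategies start by selfing the F1 into an F2 of `f2_size` plants and
applying **F2 enrichment**: discard every plant homozygous for a non-target
allele at any segregating target locus. Retained plants all have non-zero
probability of yielding the target; discarded plants have exactly zero. An
empty retained set is a reported outcome (zero targets), not an error.

* **F2–DH** — `final_size` DH lines are allocated round-robin over the
  retained plants (near-equal contribution; the equal-bulk convention
  minimises allocation variance), then selected for the homozygous target.
* **RIL** — retained F2 plants contribute equally to an F3 bulk of
  `final_size`; F4–F6 are bulks of the same census with each plant a self
  seed of a uniformly drawn plant of the previous generation; selection at
  F6. Bulk sizes between F2 and F6 are a package choice (only the F2 and
  final census are fixed by the study design).
* **Modified SSD** — pedigree enrichment in the F2; each retained plant
  contributes exactly three self seeds to the F3 (census = 3 × retained,
  ≈ 715 for the 10,000-plant F2 of the DH61×DH182 cross); F4–F6 keep that
  census by drawing without replacement from the pooled
  three-seeds-per-plant bulk; selection at F6. Holding the census at the F3
  size is required for the published census to be stable across
  generations; no selection is applied between F3 and F6.

Cycle lengths: 2 years for F2–DH (glasshouse generations plus one year of
DH production), 3 years for RIL and modified SSD (one field generation per
year after the F2). One breeding cycle is simulated.

## Gain metric

`F_ad = 100·(F − TG_l)/(TG_h − TG_l)` rescales a population's mean
grain-yield genotypic value between the two extreme target genotypes
(all-decreasing and all-increasing alleles at every yield-effect locus).
`F_ad` is invariant under affine rescaling of all effects and the baseline.
The "before" population is the F2 prior to any selection; the "after"
population is the set of selected target lines. Replicates that produce no
target line leave the population unchanged and contribute zero gain — a
package choice; counting such replicates as missing instead would bias the
mean upward for low-yielding strategies. Yield effects are averaged across
environments by default; per-environment gain reports are available.

## Scenario model

The 14 prediction loci (3 yield, 6 height, 5 ear emergence) are simulated
as DH lines drawn directly from the founder F1. Scenario 1 places every
locus on its own chromosome (2^14 equally likely homozygous classes,
expected frequency 0.0061 %; the default 200,000 individuals make every
class likely to appear). Scenario 2 merges the 2D yield/height and 3A
height/flowering pairs into single inheritance units by co-locating them
(recombination fraction exactly 0), leaving 2^12 classes (0.0244 %;
default 50,000 individuals). Complete linkage was chosen over partial
linkage because the co-located pairs behave as single pleiotropic loci in
the study design; partial linkage is available through the map interface
but is not the default.

Per-year effect tables (2005–2008) are synthetic: the multi-environment
effect scaled by a trait-specific year multiplier, with the 2006 yield
multiplier negative so that a genotype carrying all favourable yield
alleles has its worst predicted yield in 2006 (an adverse season). They
demonstrate the machinery — per-environment prediction and across-year
dispersion — but the published per-year dispersion ranges cannot be
reproduced without the unpublished per-year effect estimates.

The nine packaged "ideal genotype" patterns are synthetic reconstructions
(`ideal_genotypes_synthetic.tsv`): all carry the favourable yield alleles
and near-Avalon height/flowering alleles, and exactly three (SDH2, SDH5,
SDH8) are discordant at the 3A height/flowering pair, so scenario 2 admits
six of the nine. Six equal-width yield categories are used for the
conditional height/flowering summaries (bin edges are a package choice).

## Randomness and reproducibility

Every stochastic entry point takes a master seed; replicate `i` uses a
stream derived from `(seed, i)` (PCG64/SeedSequence), so any replicate can
be reproduced in isolation and identical configurations give byte-identical
output tables. Standard errors are reported as sample SD/√reps and are
absent (not zero) for single replicates.

## Problem sizes

`scripts/acceptance.py` runs the full study conditions: 1,000 replicates
per quantity at F2 sizes 2,000–10,000 (about a minute on one CPU). The test
suite exercises the same code paths at reduced replicate counts
(30–500 depending on the Monte-Carlo variance of the statistic) and
down-scaled class-frequency checks (2^6 classes for the uniformity
chi-square); stochastic assertions use seeded streams and three-standard-
error bands around exact expectations.

## Known limitations

* No dominance, epistasis, or QTL-by-environment re-estimation; markers are
  assumed perfectly diagnostic of the QTL alleles (no flanking-marker
  error model).
* Map spacings are calibrated defaults (above), not estimates; conclusions
  that hinge on fine linkage structure should treat them as scenario
  parameters.
* Synthetic effect magnitudes make the adjusted-fitness scale and the
  scenario phenotype ranges internally consistent but not field-calibrated;
  passing tests show the machinery is correct under the stated conditions,
  not that real populations would realise these gains.
* One breeding cycle only; no recurrent selection, cost modelling, or
  phenotypic (non-marker) selection stages.
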