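# Methods

This note documents the models behind `crossqtl`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not establish about real data.

## The cross and its simulator

The package targets a two-parent haploid yeast cross: recombinant progeny
carry a mosaic of the two parental haplotypes, are genotyped by sequencing
read counts at biallelic markers, and are phenotyped by colony patch area
(mm²) with several replicates per strain and growth condition.

The simulator (`crossqtl.simulate`) generates such crosses with known
ground truth:

- **Meiosis.** Crossovers follow a no-interference Poisson process on the
  genetic map (Haldane map function): the recombinant fraction between
  markers d centiMorgans apart is (1 − e^(−2d/100))/2. Progeny are
  simulated as independent spores via a Markov chain along each chromosome
  (fair coin at the first marker, phase switch with the Haldane fraction
  between adjacent markers), which reproduces all pairwise recombinant
  fractions of the Poisson model. Tetrad structure (2:2 segregation within
  a tetrad) is not simulated; it does not affect marker-level single-locus
  mapping. The default map is 16 chromosomes totalling ~4,400 cM — a
  conventional yeast figure, with length and a 537-marker budget
  apportioned by physical chromosome size. Marker base-pair coordinates
  use a nominal 2.9 kb/cM.
- **Disomy.** Each progeny carries an extra chromosome I with probability
  `disome_fraction` (default 0.5, matching a disome segregating ~1:1
  through the cross), drawn independently per progeny.
- **Sequencing.** Read depth per strain × marker is negative-binomial with
  mean `mean_depth` (default 20) and variance μ + φμ² (φ =
  `depth_dispersion`, default 0.3; φ = 0 gives Poisson), reflecting the
  over-dispersion of RAD-seq coverage. Each read reports the wrong parental
  base with probability `error_rate` (default 0.002). Chromosome I markers
  of disomic strains get twice the expected depth; with `het_disomes=True`
  their reads split evenly between the parental bases (a heterozygous
  disome).
- **Phenotypes.** Each replicate is `max(floor draw, genetic expectation +
  noise)`: the genetic expectation is the condition baseline plus additive
  allele effects at planted loci, an optional disome penalty, and a
  per-strain polygenic background; noise is N(0, `noise_sd`²) with
  `noise_sd` = 4 mm²; the floor draw is N(`floor`, `floor_sd`²) clipped at
  zero (defaults 2 and 1 mm²). The floor is censoring (a max), not
  truncation: strains that "cannot grow" still show small positive areas,
  which is how plate images read out.
- **Polygenic background** (`residual_genetic_sd`, mm² SD per condition) is
  a per-strain genetic deviation stable across replicates. It models
  heritable variance beyond the planted loci — without it, a single
  planted locus would explain essentially all genetic variance, which no
  real cross shows. In the study-like preset the background for each
  rich-medium condition is sized from the planted locus effect d and a
  target explained fraction f via background variance = (d²/4)(1/f − 1)
  with f = 0.23/0.26/0.51/0.48 (YPD/copper/rapamycin/caffeine), so the
  locus explains a realistic share of the genetic variance.
- **Reproducibility.** A single integer seed feeds a splittable generator
  (`numpy` SeedSequence); meiosis, disomy, depth, phenotypes, drug plates
  and background each consume a fixed substream, so identical seeds give
  bit-identical outputs and stages can be varied independently.

The study-like preset (`study_like_params`) plants: a major locus on
chromosome XV with effects −9/−10.5/−18.7/−12.4/−18 mm² on
YPD/copper/rapamycin/caffeine/minimal medium, condition-specific loci on
chromosome IX (ethanol) and IV (sodium), and chromosome I disome penalties
of −1.05 (ethanol) and −2.54 mm² (caffeine).

What the simulator does **not** emulate: linkage between a drug-resistance
marker locus and real loci, sub-chromosomal CNVs, GC/mappability coverage
bias, epistasis, genotype-by-replicate interactions, and day-to-day plate
effects. Passing tests therefore demonstrate that the analysis recovers
planted structure under the stated stochastic model — not that real data
meet that model.

## Genotype calling and filters

Rules, in order:

1. A parental base is confident if the top count is ≥5× the second (a zero
   runner-up counts as confident when the top is positive — otherwise
   deep, clean positions would be uncallable); a position enters the SNP
   table iff both parents are confident and differ.
2. A progeny call is P1 iff `reads_P1 > 0` and `reads_P1 ≥ 5 × reads_P2`
   (symmetrically P2); anything else is missing. Boundaries are inclusive
   ("at least five times").
3. Markers are dropped if they have sequencing reads in <5% of strains
   (read presence, not confident calls — the read-based reading of the
   rule; matrices loaded without read information fall back to call
   presence) or if the P1:P2 call ratio falls outside [0.5, 2.0]
   (inclusive, since only deviations *beyond* two-fold are excluded);
   one-sided markers fail.
4. Strains are dropped, with reason codes, for: reads at fewer than 750
   candidate marker positions (applied before marker filtering, on the
   full candidate universe — in synthetic runs with a ~537-marker universe
   the pipeline scales the threshold by the same coverage fraction,
   750/5,848 ≈ 12.8%); day-2 growth >5 mm² on both drug-marker plates
   (undissected diploids); zero growth on rich medium at day 4; or >90%
   genotype identity (over markers called in both) with an already
   retained strain. Near-duplicate removal is a greedy scan in
   lexicographic strain order keeping the first of each pair — the choice
   of which twin to keep is arbitrary, so a deterministic convention is
   used.

Positions are 1-based throughout, per pileup convention. Calling is exactly
symmetric under swapping the parent labels, and both filters are
idempotent (verified properties).

## Aneuploidy screen

Per strain, chromosome read proportions are normalized by the across-strain
median per chromosome — except the screened chromosome (chromosome I),
whose across-strain distribution is bimodal when the disome segregates
1:1, making the median unusable; it is instead normalized by the
across-strain mean divided by 1.5, the expected population mean when half
the strains carry two copies. Each strain is then rescaled so its median
relative copy number is exactly 1. Classification: [1.5, 2.5] disome,
[0.5, 1.5) euploid (the shared endpoint 1.5 resolved in favor of disome),
outside [0.5, 2.5] unresolved (treated as a sequencing artifact).

A consequence of the half-disomic assumption: in a population with **no**
disomes, the screened chromosome normalizes to ~1.5 for every strain and
the screen over-calls disomy. The denominator encodes a prior about the
cross; the screen is not meant for populations where that prior fails.

## Genome scan

The per-marker statistic is the two-group Kruskal–Wallis H on midranks
with the tie-corrected denominator, mapped to the LOD scale as
H/(2 ln 10) — the standard correspondence for rank-based single-QTL scans.
Missing data are handled per-marker complete-case (no imputation, no
pseudomarkers; all peaks are at genotyped marker coordinates). Markers
with an empty genotype class get LOD 0 and a `defined=False` flag. Ties at
the maximum resolve to the lowest chromosome (natural order) then
position. Negative H from floating-point cancellation is clipped at zero.

Permutation thresholds shuffle the phenotype vector against intact
genotype rows, preserving the marker correlation structure; the threshold
is the ⌈(1−α)·n_perm⌉-th order statistic of the per-permutation genome-wide
maximum (the conservative empirical quantile). For this order statistic
the exact null exceedance probability is (n_perm − k + 1)/(n_perm + 1) ≈
1.01% at n_perm = 10,000, α = 0.01 — the calibration the acceptance
battery verifies empirically. The scan engine groups markers by
missingness pattern so each permutation costs one ranking plus one matrix
product per pattern; a 10,000-permutation genome-wide threshold for 412
strains × 537 markers runs in a few seconds on one CPU.

Split scans condition on a major locus: strains are partitioned by their
allele at the peak marker (missing calls ignored) and each subset is
scanned with its own permutation threshold at α/n_tests (default 0.01/12,
Bonferroni over 6 conditions × 2 subsets, with n_perm = 1,000). Subsets
smaller than 10 strains warn but compute.

## Phenotype statistics

**Floor-aware quantile normalization.** Plotting positions
q_i = (rank_i − 0.5)/n (midranks for ties) are assigned over the whole
subpopulation; μ̂ and σ̂ come from regressing the values above the 5 mm²
floor cut on Φ⁻¹(q_i); every value is replaced by μ̂ + σ̂ Φ⁻¹(q_i). The
(i − 0.5)/n convention is one of several standard plotting positions; at
n ≈ 200 the alternatives move μ̂ and σ̂ negligibly. Replacing *all* values
(not only floored ones) yields a coherent normal sample and preserves
ranks exactly; `replace_all=False` instead keeps above-floor values as
measured and only infers the floored ones — both behaviors exist because
either reading is defensible; the default is replace-all. The fit refuses
to proceed with fewer than 10 above-floor values or a non-positive σ̂.

**Heritability.** H² = 1 − σ²e/σ²s. The floor filter (measurements
>5 mm², strains with ≥2 such measurements) applies to the *within*-variance
fit only: σ²w is the residual variance of a one-way random-intercept model
fit by REML (statsmodels MixedLM), with a closed-form pooled within-strain
variance available as `method="moments"` (identical for balanced data,
used as an independent cross-check); σ²e = σ²w/n̄. σ²s is the variance of
the full population of segregant means — each strain's plain replicate
mean, or externally supplied means (e.g. quantile-normalized ones for
floored conditions: raw replicates for σ²w, normalized means for σ²s).
Restricting σ²s to the floor-filtered strain subset would truncate the
distribution of means and deflate the between-strain variance, which is
why the filter is not applied there. If every strain's replicates are
identical the REML fit is degenerate and σ²w is set to 0 directly.

**Locus variance.** Each allele subpopulation's mean is subtracted from
its members; σ²ns is the variance of the pooled centered means; the locus
explains σ²s − σ²ns, reported also as a fraction of the genetic variance
H²σ²s (the natural denominator for "proportion of genetic variance").
`explained + σ²ns = σ²s` holds exactly when the same mean vector feeds
both (the `VarianceComponents.means` field carries it). Under the null the
explained variance can come out slightly negative; it is reported as-is
with a warning, never clamped.

**Interaction ANOVA** uses a two-way fixed-effects OLS fit with Type II
sums of squares (the design is approximately balanced, so the SS type is
a minor choice) and rejects empty factor cells by name. **Group tests**
use Mann–Whitney U with midranks: exact enumeration for small tie-free
groups (< 8 per group), otherwise the tie-corrected normal approximation;
the raw difference of means in mm² is reported alongside, and
multiple-testing correction across conditions is left to the caller.
**Condition correlations** are plain Pearson coefficients over strains
present in both conditions (≥3 complete pairs, non-degenerate variance).

## Estimator choices on floored synthetic data

Two measurement conventions in the acceptance battery deserve note:

- Subpopulation mean differences are computed after per-subpopulation
  quantile normalization for conditions where a material share (>5%) of
  strain means sits below the 5 mm² cut — in the synthetic study that is
  copper, rapamycin and caffeine. Raw means in a floored subpopulation are
  biased toward the floor, so the raw difference understates the planted
  effect; the floor-aware estimator removes that censoring bias.
- The chromosome I disome penalty is measured within the non-carrier
  (unfloored) allele class at the condition's major locus. Disomy
  segregates independently of the locus, so the penalty there equals the
  population penalty, while the carrier class is floor-censored and would
  compress the pooled estimate.

## Problem sizes

The test suite and acceptance script scale their simulations to what the
statistics require rather than to the largest feasible run: planted-effect
recoveries average 20–40 replicate 412-progeny crosses (Monte-Carlo SE
well below the assertion bands), variance decompositions 6–12 crosses,
threshold calibration uses one 10,000-permutation threshold (2,000 in the
test variant) and 500 independent null datasets, and exactness checks
enumerate small instances exhaustively (read-count pairs to depth 12; all
two-group rank assignments up to 12 strains against a brute-force oracle).

## Known limitations

- Marker-level scanning only: no interval mapping, multi-QTL models, or
  epistasis scans; LOD peaks are only as fine as the marker map.
- The rank-based scan discards effect-size information; effect sizes are
  estimated separately from subpopulation means.
- The heritability decomposition assumes independent replicate errors
  within strains; shared plate/day effects would inflate H².
- The aneuploidy screen is whole-chromosome only and assumes the
  half-disomic prior for the screened chromosome (see above).
- The quantile normalization assumes each allele subpopulation is normal
  above the floor; strongly skewed or multi-modal subpopulations would be
  mis-reconstructed.
- Permutation runs are sequential; the `--threads` CLI option is accepted
  for interface stability and results are by construction independent of
  the worker count.
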