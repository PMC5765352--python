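# crossqtl

QTL mapping for two-parent haploid yeast crosses, from sequencing read
counts to variance decomposition.

Quantitative geneticists mapping growth traits in *Saccharomyces
cerevisiae* crosses face a recurring pipeline: call progeny genotypes from
sparse sequencing (RAD-seq) allele counts, screen for aneuploid segregants
by read depth, scan the genome for loci linked to a quantitative phenotype,
and decompose the phenotypic variance into genetic and measurement
components. `crossqtl` implements that pipeline for a cross of two haploid
parents (here labelled P1 and P2) phenotyped by colony patch area (mm²)
under multiple growth conditions, together with a synthetic cross simulator
that provides ground truth for every stage.

## The statistics at the core

**Genotype calling.** A parental SNP defines a marker only if, in both
parents, the most common base is at least five times the runner-up and the
two confident bases differ. A progeny call at a marker requires the winning
parent's read count to be at least five-fold the other's; markers with
reads in <5% of strains or a P1:P2 call ratio beyond two-fold of 1:1 are
dropped, and strains are dropped for low marker coverage, double drug
resistance, no growth on rich medium, or >90% genotype identity with a
retained strain.

**Aneuploidy screen.** Relative copy number of chromosome *c* in strain *s*
is the read proportion p[s,c] normalized by its across-strain median, then
rescaled so each strain's median is 1. Chromosome I — which carries a
disome segregating at ~1:1 through this cross — is instead normalized by
the across-strain mean divided by 1.5; strains with a chromosome I value in
[1.5, 2.5] are classified disomic, in [0.5, 1.5) euploid, otherwise
unresolved.

**Genome scan.** Floor-censored, bimodal growth distributions rule out
normal-theory interval mapping, so the scan statistic at each marker is the
tie-corrected Kruskal–Wallis rank statistic *H* between the two genotype
classes, reported on the LOD scale:

    LOD = H / (2 ln 10)

Genome-wide significance comes from permutation: shuffle the phenotype
vector across strains (n = 10,000, α = 0.01 by default), record the
genome-wide maximum LOD per permutation, and take the ⌈(1−α)·n⌉-th order
statistic. Secondary loci hidden behind a major-effect QTL are found by
splitting the population on the peak-marker allele and rescanning each
subset with Bonferroni-corrected thresholds.

**Variance decomposition.** Broad-sense heritability is

    H² = 1 − σ²e / σ²s,   σ²e = σ²w / n̄

where σ²s is the variance of segregant mean phenotypes, σ²w the pooled
within-segregant (replicate) variance from a one-way random-intercept REML
fit restricted to measurements >5 mm², and n̄ the mean number of retained
measurements per segregant. The genetic variance explained by a locus is
σ²s − σ²ns, where σ²ns is the variance of segregant means after
zero-centering each allele subpopulation. Floor-censored subpopulations are
first mapped onto a fitted normal (quantile normalization against the
portion growing >5 mm²).

## Worked example

`examples/simulate_and_scan.py` simulates a 412-progeny cross with a
−9 mm² allele effect planted on chromosome XV and scans the rich-medium
phenotype:

```
planted locus:       chr15_638034 (effect -9.0 mm^2)
scan peak:           chr15_638034  LOD = 17.2
threshold (a=0.01):  3.71  (7 markers above)
```

The scan's peak lands exactly at the planted marker, far above the
genome-wide 1% permutation threshold; the other markers above threshold
are neighbors linked to the same locus. The other scripts in `examples/`
demonstrate genotype calling (`genotype_calling.py`), the aneuploidy screen
(`aneuploidy_screen.py`), heritability and locus variance
(`heritability_decomposition.py`), floor-aware normalization
(`floored_normalization.py`), and the one-call pipeline
(`full_pipeline.py`). A thin CLI mirrors the stages:

```sh
crossqtl simulate --out-dir demo --seed 1
crossqtl run-all --config demo/config.yaml
```

## Layout

- `src/crossqtl/simulate.py` — synthetic cross generator (meiosis, read
  counts, phenotypes)
- `src/crossqtl/genotypes.py` — SNP table, genotype calling, marker/strain
  filters
- `src/crossqtl/ploidy.py` — coverage-based aneuploidy screen
- `src/crossqtl/scan.py` — rank-based genome scans, permutation thresholds,
  split scans
- `src/crossqtl/phenostats.py` — normalization, heritability, locus
  variance, group tests
- `src/crossqtl/io.py`, `pipeline.py`, `cli.py` — TSV formats, orchestration,
  command line
- `docs/methods.md` — model assumptions, parameter choices, and limitations
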