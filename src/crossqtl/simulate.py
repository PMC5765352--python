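"""Synthetic two-parent haploid cross simulator.

Generates crosses with the statistical structure the downstream analysis
assumes — haploid recombinant progeny genotyped by sparse read counts at
biallelic markers, an optional chromosome I disome segregating through the
cross, and colony patch-area phenotypes with additive locus effects and a
hard growth floor — so that every pipeline stage can be tested against a
known ground truth.

Model summary
-------------
* Meiosis: crossovers follow a no-interference (Poisson) process on the
  genetic map, so the recombinant fraction between two markers separated by
  d centiMorgans is the Haldane value (1 - exp(-2 d / 100)) / 2.  Progeny
  are simulated as independent spores; tetrad co-segregation is not modeled.
* Sequencing: per strain x marker read depth is negative-binomial
  (over-dispersed relative to Poisson, as in RAD-seq), and each read reports
  the wrong parental base with a fixed error probability.  Strains carrying
  an extra chromosome I receive, in expectation, twice the depth at
  chromosome I markers; heterozygous disomes split those reads evenly
  between the two parental bases.
* Phenotype: each replicate patch area (mm^2) is the maximum of a noisy
  growth floor and the strain's genetic expectation (condition baseline +
  additive allele effects + optional disome effect) plus Gaussian noise.
  The floor is a censoring mechanism, not a truncation: floored strains
  still show small positive areas.

A single integer seed drives a splittable generator; each stage (meiosis,
disomy, depth, phenotypes, drug plates) consumes its own substream, so the
stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "QtlEffect",
    "SimParams",
    "SimTruth",
    "AlleleCounts",
    "yeast_chromosomes",
    "study_like_params",
    "simulate_genotypes",
    "simulate_allele_counts",
    "simulate_phenotypes",
    "simulate_cross",
    "chromosome_read_counts",
]

# Nominal physical-to-genetic scaling for S. cerevisiae (~0.35 cM/kb,
# i.e. ~2.9 kb per cM); used only to assign marker base-pair coordinates.
BP_PER_CM = 2900

# Approximate physical sizes (kb) of the 16 S. cerevisiae chromosomes
# (R64 reference), used to apportion genetic length and marker counts.
_YEAST_CHR_KB = {
    "chr1": 230, "chr2": 813, "chr3": 317, "chr4": 1532,
    "chr5": 577, "chr6": 270, "chr7": 1091, "chr8": 562,
    "chr9": 440, "chr10": 746, "chr11": 667, "chr12": 1078,
    "chr13": 924, "chr14": 784, "chr15": 1091, "chr16": 948,
}

# Substream indices for the splittable seed.
_STREAMS = {"meiosis": 0, "disomy": 1, "depth": 2, "phenotype": 3, "drug": 4,
            "background": 5}


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome of the simulated genome."""

    name: str
    length_cm: float  # genetic length, centiMorgans
    n_markers: int

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError(
                f"chromosome {self.name!r}: marker count must be >= 1, "
                f"got {self.n_markers}"
            )
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name!r}: negative genetic length")


@dataclass(frozen=True)
class QtlEffect:
    """Additive allele effect planted at one marker for one condition.

    ``effect_mm2`` is added to the expected patch area of strains carrying
    the P2 allele at ``marker``; P1 carriers get the condition baseline.
    ``marker`` is either an exact marker id (``chr15_643999``) or a
    chromosome plus relative map position (``chr15@0.5``), resolved to the
    nearest simulated marker.
    """

    marker: str
    condition: str
    effect_mm2: float


def yeast_chromosomes(total_cm: float = 4400.0, total_markers: int = 537) -> list[ChromosomeSpec]:
    """A conventional 16-chromosome yeast map.

    Genetic length (default 4,400 cM genome-wide) and the marker budget are
    apportioned to chromosomes in proportion to physical size, with at least
    four markers per chromosome.
    """
    kb = pd.Series(_YEAST_CHR_KB, dtype=float)
    lengths = total_cm * kb / kb.sum()
    raw = total_markers * kb / kb.sum()
    counts = np.maximum(np.floor(raw).astype(int), 4)
    # distribute the remainder to the largest fractional parts
    short = total_markers - int(counts.sum())
    if short > 0:
        order = (raw - np.floor(raw)).sort_values(ascending=False).index
        for name in order[:short]:
            counts[name] += 1
    return [
        ChromosomeSpec(name, float(lengths[name]), int(counts[name]))
        for name in kb.index
    ]


@dataclass
class SimParams:
    """Configuration of one simulated cross.

    Defaults reproduce the mapping population of the study design this
    package implements: 412 haploid progeny of a two-parent cross, ~537
    markers over 16 chromosomes, RAD-seq-like read counts, half the progeny
    disomic for chromosome I, and four replicate patch-area measurements
    per strain and condition.
    """

    n_progeny: int = 412
    chromosomes: list[ChromosomeSpec] = field(default_factory=yeast_chromosomes)
    qtl_effects: list[QtlEffect] = field(default_factory=list)
    baseline_mean: dict[str, float] = field(default_factory=lambda: {"YPD": 25.0})
    noise_sd: float = 4.0          # mm^2, replicate-to-replicate + strain residual
    floor: float = 2.0             # mm^2, minimum observable growth
    floor_sd: float = 1.0          # mm^2, noise at the floor
    mean_depth: float = 20.0       # reads per marker
    depth_dispersion: float = 0.3  # NB over-dispersion; 0 = Poisson
    error_rate: float = 0.002      # per-read wrong-parental-base probability
    disome_fraction: float = 0.5   # chromosome I disome probability per progeny
    disome_effects: dict[str, float] = field(default_factory=dict)  # mm^2 per condition
    # polygenic background: per-strain genetic deviation (mm^2 SD, per condition),
    # stable across replicates; models heritable variance beyond the planted loci
    residual_genetic_sd: dict[str, float] = field(default_factory=dict)
    het_disomes: bool = False      # disome chrI reads split between parents
    n_replicates: int = 4
    day: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if not (0.0 <= self.disome_fraction <= 1.0):
            raise ValueError("disome_fraction must be in [0, 1]")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(self.baseline_mean)

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage substream of the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS[stage]]
        )

    def replace(self, **kw) -> "SimParams":
        return dataclasses.replace(self, **kw)


def study_like_params(seed: int = 0, **overrides) -> SimParams:
    """A cross parameterized like the mapping study's seven growth conditions.

    A major-effect locus on chromosome XV depresses growth of P2-allele
    carriers on the four YPD-based media and on minimal medium (SD);
    condition-specific loci act on ethanol (chromosome IX) and sodium
    (chromosome IV); the chromosome I disome carries small growth penalties
    on ethanol and caffeine.  Effect sizes (9 / 10.5 / 18.7 / 12.4 mm^2,
    1.05 / 2.54 mm^2) are the subpopulation mean differences the analysis
    should recover.

    Beyond the major locus, each condition carries polygenic background
    variance (``residual_genetic_sd``) sized so the major locus explains the
    study-like fraction of the genetic variance (0.23 / 0.26 / 0.51 / 0.48
    on the four rich-medium conditions): with a balanced locus of effect d
    explaining d^2/4, a target fraction f implies background variance
    (d^2/4)(1/f - 1).
    """
    major = "chr15@0.55"

    def background(effect: float, fraction: float) -> float:
        return float(np.sqrt(effect**2 / 4 * (1 / fraction - 1)))

    params = SimParams(
        qtl_effects=[
            QtlEffect(major, "YPD", -9.0),
            QtlEffect(major, "copper", -10.5),
            QtlEffect(major, "rapamycin", -18.7),
            QtlEffect(major, "caffeine", -12.4),
            QtlEffect(major, "SD", -18.0),
            QtlEffect("chr9@0.93", "ethanol", -5.0),
            QtlEffect("chr4@0.34", "sodium", -11.0),
        ],
        baseline_mean={
            "YPD": 25.0, "copper": 24.0, "rapamycin": 25.0,
            "caffeine": 20.0, "ethanol": 14.0, "sodium": 18.0, "SD": 22.0,
        },
        disome_effects={"ethanol": -1.05, "caffeine": -2.54},
        residual_genetic_sd={
            "YPD": background(9.0, 0.23),
            "copper": background(10.5, 0.26),
            "rapamycin": background(18.7, 0.51),
            "caffeine": background(12.4, 0.48),
            "SD": 2.0, "ethanol": 2.0, "sodium": 3.0,
        },
        seed=seed,
    )
    return params.replace(**overrides) if overrides else params


@dataclass
class SimTruth:
    """Ground truth of one simulated cross.

    ``genotypes`` is complete (no missing calls): strains in rows, markers in
    columns, values ``"P1"``/``"P2"``.  ``markers`` carries chromosome,
    bp position and map position per marker.  ``expected_means`` is the
    pre-floor genetic expectation per strain x condition.
    """

    genotypes: pd.DataFrame
    markers: pd.DataFrame            # index marker_id; chrom, pos, cm
    disome_flags: pd.Series          # strain -> bool
    qtl_effects: list[QtlEffect]     # with resolved marker ids
    expected_means: pd.DataFrame     # strain x condition

    @property
    def strains(self) -> pd.Index:
        return self.genotypes.index

    def marker_ids(self, chrom: str | None = None) -> pd.Index:
        if chrom is None:
            return self.markers.index
        return self.markers.index[self.markers["chrom"] == chrom]


@dataclass
class AlleleCounts:
    """Read counts of the two parental bases per strain x marker."""

    p1: pd.DataFrame  # strains x markers, reads supporting the P1 base
    p2: pd.DataFrame  # strains x markers, reads supporting the P2 base

    def __post_init__(self) -> None:
        if not (self.p1.index.equals(self.p2.index) and self.p1.columns.equals(self.p2.columns)):
            raise ValueError("p1 and p2 count tables must share index and columns")

    @property
    def depth(self) -> pd.DataFrame:
        return self.p1 + self.p2

    @property
    def strains(self) -> pd.Index:
        return self.p1.index

    @property
    def markers(self) -> pd.Index:
        return self.p1.columns


def _marker_table(chromosomes: list[ChromosomeSpec]) -> pd.DataFrame:
    rows = []
    for spec in chromosomes:
        m = spec.n_markers
        cm = np.linspace(0.0, spec.length_cm, m) if m > 1 else np.array([spec.length_cm / 2])
        span_bp = max(spec.length_cm, 1.0) * BP_PER_CM
        bp = np.round(np.linspace(1, span_bp, m)).astype(int) if m > 1 else np.array(
            [int(span_bp // 2) + 1]
        )
        for j in range(m):
            rows.append((f"{spec.name}_{bp[j]}", spec.name, int(bp[j]), float(cm[j])))
    df = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "cm"]).set_index("marker")
    if df.index.has_duplicates:
        raise ValueError("marker positions collide; increase chromosome length or reduce markers")
    return df


def _resolve_marker(spec: str, markers: pd.DataFrame) -> str:
    """Resolve ``chrN_pos`` or ``chrN@frac`` to a marker id."""
    if spec in markers.index:
        return spec
    if "@" in spec:
        chrom, frac = spec.split("@", 1)
        sub = markers[markers["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no markers on chromosome {chrom!r}")
        target = float(frac) * sub["cm"].max()
        return (sub["cm"] - target).abs().idxmin()
    raise KeyError(f"unknown marker {spec!r}")


def simulate_genotypes(params: SimParams) -> SimTruth:
    """Simulate complete haploid progeny genotypes and disome flags.

    Each progeny chromosome is a mosaic of P1/P2 blocks: the first marker's
    allele is a fair coin and the phase switches between adjacent markers
    with the Haldane recombinant fraction for their map distance.  Under the
    Poisson crossover model this Markov construction has exactly the right
    pairwise recombinant fractions.
    """
    markers = _marker_table(params.chromosomes)
    rng = params.rng("meiosis")
    n = params.n_progeny
    cols = []
    for spec in params.chromosomes:
        m = spec.n_markers
        cm = markers.loc[markers["chrom"] == spec.name, "cm"].to_numpy()
        rf = 0.5 * (1.0 - np.exp(-2.0 * np.diff(cm) / 100.0))
        first = rng.random(n) < 0.5
        switches = rng.random((n, m - 1)) < rf[None, :] if m > 1 else np.empty((n, 0), bool)
        geno = np.logical_xor.accumulate(
            np.concatenate([first[:, None], switches], axis=1), axis=1
        )
        cols.append(geno)
    code = np.concatenate(cols, axis=1)  # False=P1, True=P2
    strains = pd.Index([f"seg{i:04d}" for i in range(n)], name="strain")
    genotypes = pd.DataFrame(
        np.where(code, "P2", "P1"), index=strains, columns=markers.index
    )
    disome = pd.Series(
        params.rng("disomy").random(n) < params.disome_fraction, index=strains, name="chr1_disome"
    )

    effects = [
        QtlEffect(_resolve_marker(e.marker, markers), e.condition, e.effect_mm2)
        for e in params.qtl_effects
    ]
    expected = pd.DataFrame(
        {c: params.baseline_mean[c] for c in params.conditions},
        index=strains, dtype=float,
    )
    for e in effects:
        if e.condition not in expected.columns:
            raise KeyError(f"effect condition {e.condition!r} has no baseline_mean")
        carrier = genotypes[e.marker].eq("P2").to_numpy()
        expected.loc[carrier, e.condition] += e.effect_mm2
    for cond, eff in params.disome_effects.items():
        if cond in expected.columns:
            expected.loc[disome.to_numpy(), cond] += eff
    if params.residual_genetic_sd:
        brng = params.rng("background")
        for cond in expected.columns:  # fixed order keeps substreams stable
            sd = params.residual_genetic_sd.get(cond, 0.0)
            if sd > 0:
                expected[cond] += brng.normal(0.0, sd, size=n)
    return SimTruth(genotypes, markers, disome, effects, expected)


def simulate_allele_counts(truth: SimTruth, params: SimParams) -> AlleleCounts:
    """Sample sequencing read counts of the two parental bases.

    Depth is negative-binomial with mean ``mean_depth`` and variance
    mu + dispersion * mu^2 (Poisson when dispersion = 0); chromosome I
    markers of disomic strains get twice the expected depth.  Each read
    reports the true parent's base with probability 1 - error_rate, except
    in heterozygous disomes (``het_disomes=True``), whose chromosome I reads
    split evenly between the parents.
    """
    rng = params.rng("depth")
    n, m = truth.genotypes.shape
    mu = np.full((n, m), float(params.mean_depth))
    chr1 = truth.markers["chrom"].eq(params.chromosomes[0].name).to_numpy()
    mu[np.ix_(truth.disome_flags.to_numpy(), chr1)] *= 2.0

    if params.mean_depth == 0:
        depth = np.zeros((n, m), dtype=int)
    elif params.depth_dispersion == 0:
        depth = rng.poisson(mu)
    else:
        k = 1.0 / params.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + mu))

    p_correct = np.full((n, m), 1.0 - params.error_rate)
    if params.het_disomes:
        p_correct[np.ix_(truth.disome_flags.to_numpy(), chr1)] = 0.5
    true_reads = rng.binomial(depth, p_correct)
    is_p1 = truth.genotypes.to_numpy() == "P1"
    p1 = np.where(is_p1, true_reads, depth - true_reads)
    return AlleleCounts(
        pd.DataFrame(p1, index=truth.strains, columns=truth.markers.index),
        pd.DataFrame(depth - p1, index=truth.strains, columns=truth.markers.index),
    )


def simulate_phenotypes(
    truth: SimTruth, params: SimParams, drug_plates: bool = False
) -> pd.DataFrame:
    """Sample replicate patch areas (long table: strain, condition, day, replicate, area).

    Each replicate is ``max(floor draw, genetic expectation + noise)`` where
    the floor draw is N(floor, floor_sd^2) clipped at zero.  With
    ``drug_plates=True`` the table additionally carries day-2 areas on the
    two drug-marker plates (each strain resistant to exactly one drug), as
    used by the strain-quality filters.
    """
    rng = params.rng("phenotype")
    n = len(truth.strains)
    frames = []
    for cond in truth.expected_means.columns:
        mean = truth.expected_means[cond].to_numpy()[:, None]
        noise = rng.normal(0.0, params.noise_sd, size=(n, params.n_replicates))
        floor = np.clip(
            rng.normal(params.floor, params.floor_sd, size=(n, params.n_replicates)), 0.0, None
        )
        area = np.maximum(floor, mean + noise)
        frames.append(
            pd.DataFrame(
                {
                    "strain": np.repeat(truth.strains, params.n_replicates),
                    "condition": cond,
                    "day": params.day,
                    "replicate": np.tile(np.arange(1, params.n_replicates + 1), n),
                    "area": area.ravel(),
                }
            )
        )
    if drug_plates:
        drng = params.rng("drug")
        resistant_first = drng.random(n) < 0.5
        for plate, res in (("YPD+Kan", resistant_first), ("YPD+Nat", ~resistant_first)):
            area = np.where(
                res, drng.normal(10.0, 1.0, n), np.clip(drng.normal(1.0, 0.4, n), 0.0, None)
            )
            frames.append(
                pd.DataFrame(
                    {"strain": truth.strains, "condition": plate, "day": 2,
                     "replicate": 1, "area": area}
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["area"] = out["area"].round(6)
    return out


def simulate_cross(params: SimParams, drug_plates: bool = False):
    """Convenience wrapper: genotypes, allele counts and phenotypes in one call."""
    truth = simulate_genotypes(params)
    counts = simulate_allele_counts(truth, params)
    pheno = simulate_phenotypes(truth, params, drug_plates=drug_plates)
    return truth, counts, pheno


def chromosome_read_counts(counts: AlleleCounts, markers: pd.DataFrame) -> pd.DataFrame:
    """Total aligned-read counts per strain x chromosome (input to the ploidy screen)."""
    chrom = markers.loc[counts.markers, "chrom"]
    return counts.depth.T.groupby(chrom, sort=False).sum().T
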