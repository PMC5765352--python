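"""Nonparametric single-locus genome scans with permutation thresholds.

The scan statistic at each marker is the Kruskal-Wallis rank statistic H
(midranks for ties, tie-corrected denominator) comparing phenotype ranks
between the two parental genotype classes, expressed on the LOD scale as
H / (2 ln 10) — the standard mapping of the rank-based statistic used for
nonparametric single-QTL scans.  Being rank-based, the scan is invariant
under any strictly monotone transform of the phenotype, which is what makes
it appropriate for floor-censored, bimodal growth distributions.

Genome-wide significance is assessed by permutation: the phenotype vector
is shuffled against whole genotype rows (preserving the marker correlation
structure), the genome-wide maximum LOD is recorded per permutation, and
the threshold is the ceil((1-alpha) * n_perm)-th order statistic.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genotypes import GenotypeMatrix

__all__ = [
    "ScanResult",
    "kw_lod",
    "genome_scan",
    "permutation_threshold",
    "split_scan",
]

LOD_SCALE = 2.0 * math.log(10.0)


@dataclass
class ScanResult:
    """Per-marker LOD profile with optional permutation threshold.

    ``table`` has one row per marker (chrom, pos, lod, n_used, defined);
    ``defined`` is False where a genotype class was empty and the LOD was
    reported as 0.  ``peak`` is the max-LOD marker, ties broken by lowest
    chromosome (input order) then position.
    """

    table: pd.DataFrame
    peak: str
    threshold: float | None = None
    alpha: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    @property
    def lod(self) -> pd.Series:
        return self.table["lod"]

    @property
    def peak_lod(self) -> float:
        return float(self.table.loc[self.peak, "lod"])

    def above_threshold(self) -> pd.Series:
        if self.threshold is None:
            raise ValueError("scan has no permutation threshold")
        return self.table["lod"] > self.threshold

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        if self.threshold is not None:
            out["above_threshold"] = out["lod"] > self.threshold
        return out


class _ScanEngine:
    """Vectorized KW-LOD over markers, reused across permutations.

    Markers are grouped by their genotype-missingness pattern; within a
    group, ranking the phenotype once serves every marker via one matrix
    product of ranks against the genotype-class indicators.
    """

    def __init__(self, codes: np.ndarray):
        if codes.ndim != 2:
            raise ValueError("codes must be strains x markers")
        self.n_strains, self.n_markers = codes.shape
        miss = codes == 0
        _, inverse = np.unique(miss, axis=1, return_inverse=True)
        self.groups = []
        for g in np.unique(inverse):
            cols = np.flatnonzero(inverse == g)
            idx = np.flatnonzero(~miss[:, cols[0]])
            sub = codes[np.ix_(idx, cols)]
            ind1 = (sub == 1).astype(np.float64)
            ind2 = (sub == 2).astype(np.float64)
            self.groups.append((cols, idx, ind1, ind2, ind1.sum(0), ind2.sum(0)))

    def lods(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (lod, n_used, defined) per marker for one phenotype vector."""
        lod = np.zeros(self.n_markers)
        n_used = np.zeros(self.n_markers, dtype=int)
        defined = np.zeros(self.n_markers, dtype=bool)
        for cols, idx, ind1, ind2, n1, n2 in self.groups:
            vals = values[idx]
            n = vals.size
            n_used[cols] = n
            ok = (n1 > 0) & (n2 > 0)
            defined[cols] = ok
            if n < 2 or not ok.any():
                continue
            ranks = rankdata(vals)
            _, counts = np.unique(vals, return_counts=True)
            tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
            if tie <= 0:  # all values identical
                continue
            r1 = ranks @ ind1
            r2 = ranks @ ind2
            with np.errstate(divide="ignore", invalid="ignore"):
                h = 12.0 / (n * (n + 1)) * (r1**2 / n1 + r2**2 / n2) - 3.0 * (n + 1)
            h = np.where(ok, h / tie, 0.0)
            lod[cols] = np.clip(h, 0.0, None) / LOD_SCALE
        return lod, n_used, defined

    def max_lod(self, values: np.ndarray) -> float:
        return float(self.lods(values)[0].max(initial=0.0))


def _codes_from_genotype(genotype) -> np.ndarray:
    arr = np.asarray(genotype, dtype=object)
    out = np.zeros(arr.shape, dtype=np.int8)
    out[arr == "P1"] = 1
    out[arr == "P2"] = 2
    return out


def kw_lod(phenotype, genotype) -> float:
    """Kruskal-Wallis LOD for one marker.

    ``phenotype`` and ``genotype`` are aligned per-strain vectors; genotype
    values outside {"P1", "P2"} and non-finite phenotypes are excluded.
    Returns H / (2 ln 10); 0 when a genotype class is empty (the scan marks
    such markers undefined).
    """
    pheno = np.asarray(phenotype, dtype=float)
    codes = _codes_from_genotype(genotype)
    keep = np.isfinite(pheno)
    engine = _ScanEngine(codes[keep][:, None])
    return float(engine.lods(pheno[keep])[0][0])


def _aligned(G: GenotypeMatrix, phenotype: pd.Series):
    """Complete-phenotype strains: genotype codes and phenotype values."""
    pheno = phenotype.reindex(G.strains).astype(float)
    keep = pheno.notna().to_numpy()
    return G.codes()[keep], pheno.to_numpy()[keep]


def _chrom_key(name: str):
    """Natural chromosome order: numeric suffix when present, else lexicographic."""
    m = re.search(r"(\d+)$", str(name))
    return (0, int(m.group(1)), "") if m else (1, 0, str(name))


def _pick_peak(table: pd.DataFrame) -> str:
    top = table[table["lod"] == table["lod"].max()]
    return min(top.index, key=lambda m: (_chrom_key(top.at[m, "chrom"]), top.at[m, "pos"]))


def genome_scan(
    G: GenotypeMatrix,
    phenotype: pd.Series,
    n_perm: int | None = None,
    alpha: float = 0.01,
    seed: int = 0,
) -> ScanResult:
    """KW-LOD at every marker of ``G``; optionally a permutation threshold.

    ``phenotype`` is a per-strain value (e.g. a strain's mean day-4 patch
    area for one condition), indexed by strain name.  When ``n_perm`` is
    given, :func:`permutation_threshold` is run with the same data and the
    result attached.
    """
    if len(G.marker_ids) == 0:
        raise ValueError("genotype matrix has no markers")
    codes, values = _aligned(G, phenotype)
    engine = _ScanEngine(codes)
    lod, n_used, defined = engine.lods(values)
    table = pd.DataFrame(
        {
            "chrom": G.markers.loc[G.marker_ids, "chrom"].to_numpy(),
            "pos": G.markers.loc[G.marker_ids, "pos"].to_numpy(),
            "lod": lod,
            "n_used": n_used,
            "defined": defined,
        },
        index=G.marker_ids.rename("marker"),
    )
    result = ScanResult(table, peak=_pick_peak(table))
    if n_perm is not None:
        result.threshold = permutation_threshold(G, phenotype, n_perm, alpha, seed)
        result.alpha, result.n_perm, result.seed = alpha, n_perm, seed
    return result


def permutation_threshold(
    G: GenotypeMatrix,
    phenotype: pd.Series,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold at level ``alpha`` by phenotype permutation.

    Phenotypes are shuffled across strains while genotype rows stay intact;
    the threshold is the ceil((1-alpha) * n_perm)-th order statistic of the
    per-permutation genome-wide maximum LOD.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    codes, values = _aligned(G, phenotype)
    engine = _ScanEngine(codes)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        maxima[i] = engine.max_lod(rng.permutation(values))
    maxima.sort()
    return float(maxima[math.ceil((1.0 - alpha) * n_perm) - 1])


def split_scan(
    G: GenotypeMatrix,
    phenotype: pd.Series,
    split_marker: str,
    n_perm: int = 1000,
    alpha: float = 0.01,
    n_tests: int = 12,
    seed: int = 0,
) -> dict[str, ScanResult]:
    """Secondary scans after conditioning on the major-effect locus.

    Strains are split by their allele at ``split_marker`` (missing calls
    ignored) and each subset is scanned independently, with its own
    permutation threshold at the Bonferroni-corrected level
    ``alpha / n_tests``.  Subsets smaller than 10 strains trigger a warning
    but are still scanned.
    """
    if split_marker not in G.marker_ids:
        raise KeyError(f"split marker {split_marker!r} not in genotype matrix")
    calls = G.calls[split_marker]
    out: dict[str, ScanResult] = {}
    for k, allele in enumerate(("P1", "P2")):
        strains = calls.index[calls == allele]
        if len(strains) == 0:
            raise ValueError(f"no strains carry the {allele} allele at {split_marker}")
        if len(strains) < 10:
            warnings.warn(
                f"{allele} subset at {split_marker} has only {len(strains)} strains",
                stacklevel=2,
            )
        sub = GenotypeMatrix(
            G.calls.loc[strains],
            G.markers,
            strain_meta=G.strain_meta.loc[strains].copy(),
            marker_meta=G.marker_meta.copy(),
        )
        out[allele] = genome_scan(
            sub, phenotype, n_perm=n_perm, alpha=alpha / n_tests, seed=seed + k
        )
    return out
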