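"""Parental SNP table construction and progeny genotype calling.

All calling and filtering rules follow the RAD-seq protocol of the mapping
study: a parental base is confident only when the top base count is at least
five times the runner-up; a progeny call requires the winning parent's base
count to be at least five times the other parent's; markers must have reads
in at least 5% of strains and a P1:P2 call ratio within twofold of 1:1;
strains are dropped for poor marker coverage, double drug resistance, no
growth on rich medium, or near-identity to an already retained strain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import AlleleCounts

__all__ = [
    "ParentalSNPTable",
    "GenotypeMatrix",
    "build_parental_snp_table",
    "call_progeny_genotypes",
    "filter_markers",
    "filter_strains",
]

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
CONFIDENCE_FOLD = 5.0   # top base count must be >= 5x runner-up
CALL_FOLD = 5.0         # winning parent's reads must be >= 5x the other's
MIN_READ_FRACTION = 0.05
RATIO_LIMIT = 2.0       # P1:P2 call ratio must lie in [1/2, 2]

REASON_CODES = ("low_coverage", "drug_double_resistant", "no_growth", "near_duplicate")


@dataclass
class ParentalSNPTable:
    """Positions where both parents carry a confident, differing base."""

    records: pd.DataFrame  # columns chrom, pos, base_p1, base_p2; index marker id

    def __post_init__(self) -> None:
        df = self.records
        if (df["base_p1"] == df["base_p2"]).any():
            raise ValueError("SNP table contains non-polymorphic records")
        if df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise ValueError(f"duplicate position {dup['chrom']}:{dup['pos']}")

    @property
    def marker_ids(self) -> pd.Index:
        return self.records.index

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GenotypeMatrix:
    """Strain x marker parental calls with filtering provenance.

    ``calls`` holds ``"P1"``/``"P2"``/``NaN`` for retained strains and
    markers only; dropped strains stay in ``strain_meta`` with a reason
    code, dropped markers in ``marker_meta``.  ``strain_covered`` is the
    number of candidate marker positions with any sequencing reads per
    strain (the coverage screen operates on this, before marker filtering);
    ``marker_read_strains`` is the number of strains with any reads per
    marker.
    """

    calls: pd.DataFrame
    markers: pd.DataFrame                      # index marker id; chrom, pos
    strain_meta: pd.DataFrame = None           # retained flag, reason
    marker_meta: pd.DataFrame = None           # retained flag, reason
    strain_covered: pd.Series | None = None
    marker_read_strains: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = self.calls.columns.difference(self.markers.index)
        if len(missing):
            raise ValueError(f"calls at markers absent from marker table: {list(missing)[:5]}")
        if self.strain_meta is None:
            self.strain_meta = pd.DataFrame(
                {"retained": True, "reason": ""}, index=self.calls.index
            )
        if self.marker_meta is None:
            self.marker_meta = pd.DataFrame(
                {"retained": True, "reason": ""}, index=self.calls.columns
            )

    @property
    def strains(self) -> pd.Index:
        return self.calls.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.calls.columns

    def codes(self) -> np.ndarray:
        """int8 matrix: 0 missing, 1 P1, 2 P2."""
        arr = self.calls.to_numpy(dtype=object)
        out = np.zeros(arr.shape, dtype=np.int8)
        out[arr == "P1"] = 1
        out[arr == "P2"] = 2
        return out

    def dropped(self, reason: str | None = None) -> pd.Index:
        meta = self.strain_meta
        mask = ~meta["retained"]
        if reason is not None:
            mask &= meta["reason"].eq(reason)
        return meta.index[mask]


def _confident_base(counts: pd.DataFrame) -> pd.Series:
    """Most common base per position, NaN unless >= 5x the runner-up.

    A runner-up count of zero counts as confident whenever the top count is
    positive; otherwise high-depth clean positions would be uncallable.
    """
    mat = counts[list(BASES)].to_numpy(dtype=float)
    order = np.argsort(mat, axis=1)
    top = mat[np.arange(len(mat)), order[:, -1]]
    second = mat[np.arange(len(mat)), order[:, -2]]
    ok = (top > 0) & ((second == 0) | (top >= CONFIDENCE_FOLD * second))
    base = np.array(BASES)[order[:, -1]]
    return pd.Series(np.where(ok, base, None), index=counts.index)


def _check_base_counts(counts: pd.DataFrame, label: str) -> pd.DataFrame:
    for col in ("chrom", "pos", *BASES):
        if col not in counts.columns:
            raise ValueError(f"{label}: missing column {col!r}")
    bad = counts[list(BASES)].lt(0).any(axis=1)
    if bad.any():
        row = counts[bad].iloc[0]
        raise ValueError(f"{label}: negative count at {row['chrom']}:{row['pos']}")
    if counts.duplicated(["chrom", "pos"]).any():
        row = counts[counts.duplicated(["chrom", "pos"])].iloc[0]
        raise ValueError(f"{label}: duplicate position {row['chrom']}:{row['pos']}")
    return counts.set_index(["chrom", "pos"])


def build_parental_snp_table(
    base_counts_p1: pd.DataFrame, base_counts_p2: pd.DataFrame
) -> ParentalSNPTable:
    """Derive the marker universe from per-position parental base counts.

    A position becomes a marker iff both parents have a confident base
    (top count at least five times the second) and those bases differ.
    Input frames need columns chrom, pos, A, C, G, T; positions are 1-based.
    Indels are assumed excluded upstream.
    """
    c1 = _check_base_counts(base_counts_p1, "parent P1 counts")
    c2 = _check_base_counts(base_counts_p2, "parent P2 counts")
    common = c1.index.intersection(c2.index)
    b1 = _confident_base(c1.loc[common])
    b2 = _confident_base(c2.loc[common])
    keep = (b1.notna() & b2.notna() & (b1 != b2)).to_numpy()
    sel = common[keep]
    records = pd.DataFrame(
        {
            "chrom": sel.get_level_values("chrom"),
            "pos": sel.get_level_values("pos"),
            "base_p1": b1.to_numpy()[keep],
            "base_p2": b2.to_numpy()[keep],
        }
    )
    records.index = pd.Index(
        records["chrom"].astype(str) + "_" + records["pos"].astype(str), name="marker"
    )
    return ParentalSNPTable(records)


def call_progeny_genotypes(counts: AlleleCounts, snps: ParentalSNPTable) -> GenotypeMatrix:
    """Assign each strain x marker the majority parent, at five-fold confidence.

    The call is P1 when reads of the P1 base are positive and at least five
    times the P2-base reads; symmetrically for P2; anything else (including
    zero depth) is missing.
    """
    unknown = counts.markers.difference(snps.marker_ids)
    if len(unknown):
        raise ValueError(
            f"allele counts at markers absent from the SNP table: {list(unknown)[:5]}"
        )
    n1 = counts.p1.to_numpy(dtype=np.int64)
    n2 = counts.p2.to_numpy(dtype=np.int64)
    call_p1 = (n1 > 0) & (n1 >= CALL_FOLD * n2)
    call_p2 = (n2 > 0) & (n2 >= CALL_FOLD * n1)
    calls = pd.DataFrame(
        np.select([call_p1, call_p2], ["P1", "P2"], default=None),
        index=counts.strains, columns=counts.markers,
    )
    markers = snps.records.loc[counts.markers, ["chrom", "pos"]]
    return GenotypeMatrix(
        calls,
        markers,
        strain_covered=pd.Series((n1 + n2 > 0).sum(axis=1), index=counts.strains),
        marker_read_strains=pd.Series((n1 + n2 > 0).sum(axis=0), index=counts.markers),
    )


def filter_markers(G: GenotypeMatrix) -> GenotypeMatrix:
    """Drop markers with reads in <5% of strains or a skewed call ratio.

    The read-coverage clause counts strains with any sequencing reads at the
    marker (per-marker read presence, not confident calls); when the matrix
    was loaded without read information, strains with a call stand in.  The
    call-ratio clause keeps markers whose P1:P2 call ratio lies within
    [0.5, 2.0] (boundaries inclusive); a marker with zero calls for either
    parent fails it.
    """
    n_strains = len(G.strains)
    if G.marker_read_strains is not None:
        read_strains = G.marker_read_strains.loc[G.marker_ids]
    else:
        read_strains = G.calls.notna().sum(axis=0)
    n_p1 = G.calls.eq("P1").sum(axis=0)
    n_p2 = G.calls.eq("P2").sum(axis=0)
    coverage_ok = read_strains >= MIN_READ_FRACTION * n_strains
    ratio_ok = (n_p1 > 0) & (n_p2 > 0) & (n_p1 <= RATIO_LIMIT * n_p2) & (n_p2 <= RATIO_LIMIT * n_p1)
    keep = coverage_ok & ratio_ok

    marker_meta = G.marker_meta.copy()
    reason = np.where(~coverage_ok, "low_read_fraction", "call_ratio")
    newly_dropped = G.marker_ids[~keep]
    marker_meta.loc[newly_dropped, "retained"] = False
    marker_meta.loc[newly_dropped, "reason"] = reason[~keep.to_numpy()]
    if len(newly_dropped):
        log.info("filter_markers: dropped %d of %d markers", len(newly_dropped), len(keep))
    return replace(
        G,
        calls=G.calls.loc[:, keep],
        markers=G.markers,
        marker_meta=marker_meta,
    )


def _similarity_drops(calls: pd.DataFrame, threshold: float) -> list[str]:
    """Greedy near-duplicate removal in lexicographic strain order.

    Identity is the fraction of agreeing calls over markers called in both
    strains; the first strain of each near-identical pair is kept.
    """
    order = sorted(calls.index)
    arr = calls.loc[order].to_numpy(dtype=object)
    code = np.zeros(arr.shape, dtype=np.int8)
    code[arr == "P1"] = 1
    code[arr == "P2"] = 2
    kept: list[int] = []
    dropped: list[str] = []
    for i in range(len(order)):
        dup = False
        for j in kept:
            both = (code[i] != 0) & (code[j] != 0)
            n_both = int(both.sum())
            if n_both == 0:
                continue
            ident = float((code[i][both] == code[j][both]).mean())
            if ident > threshold:
                dup = True
                break
        if dup:
            dropped.append(order[i])
        else:
            kept.append(i)
    return dropped


def filter_strains(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    min_markers: int = 750,
    drug_area_cut: float = 5.0,
    similarity_threshold: float = 0.90,
    checks: tuple[str, ...] = REASON_CODES,
) -> GenotypeMatrix:
    """Drop strains failing the mapping-set quality screens, with reason codes.

    Checks (selectable via ``checks``, applied in order):

    * ``low_coverage`` — reads at fewer than ``min_markers`` candidate
      positions, evaluated on the pre-marker-filter coverage counts;
    * ``drug_double_resistant`` — day-2 area above ``drug_area_cut`` mm^2 on
      both YPD+Kan and YPD+Nat (indicating an undissected diploid);
    * ``no_growth`` — zero area on YPD at day 4;
    * ``near_duplicate`` — genotype identity above ``similarity_threshold``
      with an already retained strain, over markers called in both.

    ``pheno`` is the long phenotype table (strain, condition, day,
    replicate, area); the conditions a selected check needs must be present.
    """
    meta = G.strain_meta.copy()
    active = pd.Series(True, index=G.strains)

    def mark(mask: pd.Series, reason: str) -> None:
        hit = active & mask.reindex(G.strains, fill_value=False)
        meta.loc[hit[hit].index, ["retained", "reason"]] = [False, reason]
        active[hit] = False
        if hit.any():
            log.info("filter_strains: dropped %d strains (%s)", int(hit.sum()), reason)

    def plate_mean(condition: str, day: int) -> pd.Series:
        sub = pheno[(pheno["condition"] == condition) & (pheno["day"] == day)]
        if sub.empty:
            raise ValueError(
                f"phenotype table lacks condition {condition!r} at day {day}"
            )
        return sub.groupby("strain")["area"].mean()

    if "low_coverage" in checks:
        if G.strain_covered is None:
            raise ValueError("coverage check requested but strain_covered is unavailable")
        mark(G.strain_covered < min_markers, "low_coverage")
    if "drug_double_resistant" in checks:
        kan = plate_mean("YPD+Kan", 2)
        nat = plate_mean("YPD+Nat", 2)
        both = (kan > drug_area_cut) & nat.reindex(kan.index).gt(drug_area_cut)
        mark(both, "drug_double_resistant")
    if "no_growth" in checks:
        mark(plate_mean("YPD", 4).eq(0.0), "no_growth")
    if "near_duplicate" in checks:
        dup = _similarity_drops(G.calls.loc[active[active].index], similarity_threshold)
        mark(pd.Series(True, index=dup), "near_duplicate")

    return replace(
        G,
        calls=G.calls.loc[active[active].index],
        strain_meta=meta,
        strain_covered=None if G.strain_covered is None
        else G.strain_covered.loc[active[active].index],
    )
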