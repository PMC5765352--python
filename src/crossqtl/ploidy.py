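"""Coverage-based aneuploidy screen.

Relative chromosome copy numbers are estimated from the proportion of a
strain's aligned reads falling on each chromosome, normalized across
strains, and chromosome I disomy is classified from the resulting value.
Chromosome I gets a special denominator because the disome segregates at
2:2 through the cross — about half the progeny carry the extra copy, so the
across-strain median is not a haploid baseline; instead the across-strain
mean is divided by 1.5 (the expected population mean when half the strains
are disomic).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PloidyReport", "relative_copy_number", "CHR1_CLASSES"]

CHR1_CLASSES = ("euploid", "disome", "unresolved")


@dataclass
class PloidyReport:
    """Relative copy numbers (strain x chromosome, ~1 for euploid) and chrI calls."""

    copy_number: pd.DataFrame
    chr1_class: pd.Series  # strain -> euploid | disome | unresolved
    chr1: str              # name of the chromosome screened for disomy

    def disomes(self) -> pd.Index:
        return self.chr1_class.index[self.chr1_class == "disome"]


def classify_chr1(r: float) -> str:
    """Classify a chromosome I relative copy number.

    [1.5, 2.5] is a disome and [0.5, 1.5) euploid/haploid (the shared
    endpoint resolved in favor of disome); values outside [0.5, 2.5] are
    taken to reflect sequencing artifacts and left unresolved.
    """
    if 1.5 <= r <= 2.5:
        return "disome"
    if 0.5 <= r < 1.5:
        return "euploid"
    return "unresolved"


def relative_copy_number(read_counts: pd.DataFrame, chr1: str | None = None) -> PloidyReport:
    """Estimate relative chromosome copy numbers from per-chromosome read counts.

    Steps: (1) convert counts to within-strain proportions; (2) normalize
    each chromosome's proportion by its across-strain median — except the
    disomic chromosome (``chr1``, default the first column), normalized by
    the across-strain mean divided by 1.5; (3) rescale each strain so its
    median relative copy number is exactly 1; (4) classify ``chr1``.

    Parameters
    ----------
    read_counts
        Strains in rows, chromosomes in columns, aligned-read counts.
    """
    if len(read_counts) < 2:
        raise ValueError("need at least 2 strains to normalize copy numbers")
    if chr1 is None:
        chr1 = read_counts.columns[0]
    totals = read_counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"strain {bad!r} has zero total reads")
    p = read_counts.div(totals, axis=0)

    denom = p.median(axis=0)
    denom[chr1] = p[chr1].mean() / 1.5
    r = p.div(denom, axis=1)
    r = r.div(r.median(axis=1), axis=0)

    cls = r[chr1].map(classify_chr1)
    cls.name = "chr1_class"
    return PloidyReport(r, cls, chr1)
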