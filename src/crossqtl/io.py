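"""TSV file formats and pipeline configuration.

All tables are tab-delimited text with optional ``#``-prefixed metadata
lines before the header; genome coordinates are 1-based throughout.  The
combined genotype+phenotype table mirrors the layout of the study's strain
table: one row per strain, phenotype columns named ``<condition>.d<day>``
(per-strain mean area, mm^2), marker columns named ``<chrom>_<pos>`` with
calls encoded P1/P2/NA, and parents declared on a ``# parents:`` metadata
line so they can be flagged and excluded from mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, ParentalSNPTable
from .ploidy import PloidyReport
from .scan import ScanResult
from .simulate import AlleleCounts

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "read_snp_table",
    "write_snp_table",
    "read_allele_counts",
    "write_allele_counts",
    "read_phenotypes",
    "write_phenotypes",
    "read_read_counts",
    "write_read_counts",
    "write_ploidy_report",
    "write_scan_result",
    "read_genotype_phenotype_table",
    "write_genotype_phenotype_table",
]

log = logging.getLogger(__name__)

_MARKER_RE = re.compile(r"^(chr[^_\s]+)_(\d+)$")
_PHENO_RE = re.compile(r"^(.+)\.d(\d+)$")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _metadata(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def _write_tsv(df: pd.DataFrame, path, meta: dict[str, str] | None = None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


# -- parental SNP table -------------------------------------------------------

def write_snp_table(snps: ParentalSNPTable, path) -> None:
    _write_tsv(snps.records.reset_index(), path, {"table": "parental_snp"})


def read_snp_table(path) -> ParentalSNPTable:
    df = _read_tsv(path).set_index("marker")
    return ParentalSNPTable(df[["chrom", "pos", "base_p1", "base_p2"]])


# -- allele counts ------------------------------------------------------------

def write_allele_counts(counts: AlleleCounts, path) -> None:
    """Wide TSV, one strain per row, cells ``<P1 reads>,<P2 reads>``."""
    cells = counts.p1.astype(str) + "," + counts.p2.astype(str)
    _write_tsv(cells.rename_axis("strain").reset_index(), path, {"table": "allele_counts"})


def read_allele_counts(path) -> AlleleCounts:
    wide = _read_tsv(path, dtype=str).set_index("strain")
    wide.columns.name = "marker"
    p1 = wide.apply(lambda col: col.str.split(",", expand=True).astype(int)[0])
    p2 = wide.apply(lambda col: col.str.split(",", expand=True).astype(int)[1])
    return AlleleCounts(p1, p2)


# -- phenotypes (long) --------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    cols = ["strain", "condition", "day", "replicate", "area"]
    _write_tsv(pheno[cols], path, {"table": "phenotypes", "units": "mm^2"})


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df["area"] = pd.to_numeric(df["area"], errors="coerce")
    bad = df["area"].isna().sum()
    if bad:
        log.warning("read_phenotypes: %d malformed area cells set to missing", bad)
    return df


# -- per-chromosome read counts ----------------------------------------------

def write_read_counts(read_counts: pd.DataFrame, path) -> None:
    _write_tsv(read_counts.rename_axis("strain").reset_index(), path, {"table": "read_counts"})


def read_read_counts(path) -> pd.DataFrame:
    df = _read_tsv(path).set_index("strain")
    df.columns.name = "chrom"
    return df


# -- ploidy report ------------------------------------------------------------

def write_ploidy_report(report: PloidyReport, path) -> None:
    out = report.copy_number.round(4).copy()
    out["chr1_class"] = report.chr1_class
    _write_tsv(out.rename_axis("strain").reset_index(), path,
               {"table": "ploidy", "screened_chromosome": report.chr1})


# -- scan results -------------------------------------------------------------

def write_scan_result(result: ScanResult, path) -> None:
    meta = {"table": "scan", "peak": result.peak}
    if result.threshold is not None:
        meta.update(
            threshold=f"{result.threshold:.6g}",
            alpha=str(result.alpha), n_perm=str(result.n_perm), seed=str(result.seed),
        )
    out = result.to_frame()
    out["lod"] = out["lod"].round(6)
    _write_tsv(out.rename_axis("marker").reset_index(), path, meta)


# -- combined genotype + phenotype table --------------------------------------

def write_genotype_phenotype_table(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    path,
    parents: dict[str, pd.Series] | None = None,
) -> None:
    """One row per strain: phenotype means (``cond.dN`` columns) then marker calls.

    ``parents`` optionally maps parent strain names to their call vectors;
    parent rows are appended and declared in the metadata so readers can
    exclude them from mapping.
    """
    mean = (
        pheno.groupby(["strain", "condition", "day"])["area"].mean().unstack(["condition", "day"])
    )
    mean.columns = [f"{c}.d{d}" for c, d in mean.columns]
    calls = G.calls.copy()
    if parents:
        calls = pd.concat([calls, pd.DataFrame(parents).T.reindex(columns=calls.columns)])
    out = mean.reindex(calls.index).round(4).join(calls.fillna("NA"))
    meta = {"table": "genotype_phenotype"}
    if parents:
        meta["parents"] = ",".join(parents)
    _write_tsv(out.rename_axis("strain").reset_index(), path, meta)


def read_genotype_phenotype_table(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parse a combined strain table into typed genotype and phenotype tables.

    Parent rows (named on the ``# parents:`` metadata line) are flagged in
    the strain metadata and excluded from the mapping call matrix.
    Malformed genotype or phenotype cells become missing, with a logged
    count; duplicated strain IDs are rejected.
    """
    meta = _metadata(path)
    df = _read_tsv(path, dtype=str)
    if df["strain"].duplicated().any():
        dup = df.loc[df["strain"].duplicated(), "strain"].iloc[0]
        raise ValueError(f"duplicated strain ID {dup!r}")
    df = df.set_index("strain")

    marker_cols = [c for c in df.columns if _MARKER_RE.match(c)]
    pheno_cols = [c for c in df.columns if _PHENO_RE.match(c)]
    other = set(df.columns) - set(marker_cols) - set(pheno_cols)
    if other:
        raise ValueError(f"unrecognized columns: {sorted(other)[:5]}")

    parents = [p for p in meta.get("parents", "").split(",") if p]
    progeny = df.index.difference(pd.Index(parents), sort=False)

    calls = df.loc[progeny, marker_cols]
    calls.index.name = "strain"
    calls.columns.name = "marker"
    valid = calls.isin(["P1", "P2"])
    n_bad = int((~valid & calls.notna() & (calls != "NA")).sum().sum())
    if n_bad:
        log.warning("read_genotype_phenotype_table: %d malformed calls set to missing", n_bad)
    calls = calls.where(valid, other=None)

    markers = pd.DataFrame(
        [(m, *_MARKER_RE.match(m).groups()) for m in marker_cols],
        columns=["marker", "chrom", "pos"],
    ).set_index("marker")
    markers["pos"] = markers["pos"].astype(int)

    strain_meta = pd.DataFrame({"retained": True, "reason": "", "role": "progeny"},
                               index=df.index)
    present_parents = [p for p in parents if p in df.index]
    strain_meta.loc[present_parents, "role"] = "parent"
    strain_meta.loc[present_parents, "retained"] = False

    rows = []
    for col in pheno_cols:
        cond, day = _PHENO_RE.match(col).groups()
        area = pd.to_numeric(df[col], errors="coerce")
        n_bad = int(area.isna().sum() - df[col].isna().sum())
        if n_bad > 0:
            log.warning("column %s: %d malformed areas set to missing", col, n_bad)
        rows.append(pd.DataFrame(
            {"strain": df.index, "condition": cond, "day": int(day),
             "replicate": 1, "area": area.to_numpy()}
        ))
    pheno = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["strain", "condition", "day", "replicate", "area"]
    )
    G = GenotypeMatrix(calls, markers, strain_meta=strain_meta.loc[progeny])
    return G, pheno


# -- pipeline configuration ---------------------------------------------------

@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run (YAML on disk).

    ``mode="synthetic"`` simulates the cross at run time; ``mode="tables"``
    reads the four input tables.  Filter defaults match the mapping study
    (750-marker coverage screen over the full candidate-marker universe,
    5 mm^2 drug-plate cut, 90% similarity, 5 mm^2 phenotype floor cut).
    """

    mode: str = "synthetic"
    out_dir: str = "crossqtl_out"
    # synthetic mode
    n_progeny: int = 412
    sim_seed: int = 0
    # tables mode
    snp_table: str | None = None
    allele_counts: str | None = None
    phenotypes: str | None = None
    read_counts: str | None = None
    # analysis
    conditions: list[str] | None = None
    day: int = 4
    n_perm: int = 1000
    alpha: float = 0.01
    seed: int = 0
    split_n_perm: int = 1000
    n_tests: int = 12
    # filters
    min_markers: int = 750
    similarity: float = 0.90
    drug_area_cut: float = 5.0
    floor_cut: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.mode == "tables":
            for name in ("snp_table", "allele_counts", "phenotypes", "read_counts"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"tables mode requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    data = {k: v for k, v in vars(config).items() if v is not None}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
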