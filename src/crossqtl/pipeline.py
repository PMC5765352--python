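"""End-to-end orchestration: genotypes -> ploidy -> scans -> statistics.

``run_pipeline`` executes the full analysis on either a simulated cross
(``mode="synthetic"``) or user-supplied tables, writing every intermediate
table, a run log that records each dropped strain and marker with its
reason code, and a machine-readable ``summary.json``.  Stage failures abort
with the stage named; partial outputs are left in place.

The stage order follows the original protocol: the marker-coverage screen
runs on the full candidate-marker universe before marker filtering; the
drug-resistance, no-growth, and near-duplicate screens run afterwards to
define the mapping set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import io as cio
from . import phenostats as ps
from ._version import __version__
from .ploidy import relative_copy_number
from .scan import genome_scan, split_scan
from .simulate import chromosome_read_counts, simulate_cross, study_like_params

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

# drug/marker plates are quality screens, not mapped conditions
NON_MAPPED = {"YPD+Kan", "YPD+Nat"}

# coverage screen threshold as a fraction of the candidate-marker universe:
# 750 positions out of the study's 5,848 candidates
COVERAGE_FRACTION = 750 / 5848


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def _strain_phenotype(pheno: pd.DataFrame, condition: str, day: int) -> pd.Series:
    sub = pheno[(pheno["condition"] == condition) & (pheno["day"] == day)]
    return sub.groupby("strain")["area"].mean()


@_stage("inputs")
def _load_inputs(config: cio.PipelineConfig, out: Path):
    if config.mode == "synthetic":
        params = study_like_params(seed=config.sim_seed, n_progeny=config.n_progeny)
        truth, counts, pheno = simulate_cross(params, drug_plates=True)
        snps = gt.ParentalSNPTable(
            truth.markers.assign(base_p1="A", base_p2="C")[
                ["chrom", "pos", "base_p1", "base_p2"]
            ]
        )
        read_counts = chromosome_read_counts(counts, truth.markers)
        truth_dir = out / "truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        cio._write_tsv(
            truth.genotypes.rename_axis("strain").reset_index(),
            truth_dir / "genotypes.tsv", {"table": "truth_genotypes"},
        )
        cio._write_tsv(
            truth.disome_flags.rename("chr1_disome").rename_axis("strain").reset_index(),
            truth_dir / "disome_flags.tsv", {"table": "truth_disomes"},
        )
        cio._write_tsv(
            truth.expected_means.round(6).rename_axis("strain").reset_index(),
            truth_dir / "expected_means.tsv", {"table": "truth_expected_means"},
        )
        min_markers = max(1, round(COVERAGE_FRACTION * len(truth.markers)))
    else:
        snps = cio.read_snp_table(config.snp_table)
        counts = cio.read_allele_counts(config.allele_counts)
        pheno = cio.read_phenotypes(config.phenotypes)
        read_counts = cio.read_read_counts(config.read_counts)
        min_markers = config.min_markers
    return snps, counts, pheno, read_counts, min_markers


@_stage("genotypes")
def _genotype_stage(snps, counts, pheno, config, min_markers):
    G = gt.call_progeny_genotypes(counts, snps)
    n0 = len(G.strains)
    G = gt.filter_strains(
        G, pheno, min_markers=min_markers, checks=("low_coverage",)
    )
    G = gt.filter_markers(G)
    G = gt.filter_strains(
        G, pheno,
        drug_area_cut=config.drug_area_cut,
        similarity_threshold=config.similarity,
        checks=("drug_double_resistant", "no_growth", "near_duplicate"),
    )
    meta = G.strain_meta
    dropped = meta[~meta["retained"]]
    for strain, row in dropped.iterrows():
        log.info("dropped strain %s: %s", strain, row["reason"])
    for marker, row in G.marker_meta[~G.marker_meta["retained"]].iterrows():
        log.info("dropped marker %s: %s", marker, row["reason"])
    assert n0 == len(G.strains) + len(dropped), "strain counts do not reconcile"
    return G


@_stage("scans")
def _scan_stage(G, pheno, config, out: Path):
    conditions = config.conditions or sorted(
        set(pheno["condition"]) - NON_MAPPED
    )
    scans, splits = {}, {}
    for i, cond in enumerate(conditions):
        values = _strain_phenotype(pheno, cond, config.day)
        res = genome_scan(
            G, values, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed + 1000 * i,
        )
        cio.write_scan_result(res, out / f"scan_{cond}.tsv")
        scans[cond] = res
        sub = split_scan(
            G, values, res.peak, n_perm=config.split_n_perm,
            alpha=config.alpha, n_tests=config.n_tests,
            seed=config.seed + 1000 * i + 500,
        )
        for allele, sres in sub.items():
            cio.write_scan_result(sres, out / f"split_{cond}_{allele}.tsv")
        splits[cond] = sub
    return scans, splits


@_stage("statistics")
def _stats_stage(G, pheno, scans, report, config):
    stats: dict = {"conditions": {}, "correlations": {}}
    conditions = list(scans)
    for cond in conditions:
        entry: dict = {}
        reps = pheno[(pheno["condition"] == cond) & (pheno["day"] == config.day)]
        reps = reps[reps["strain"].isin(G.strains)]
        try:
            vc = ps.heritability(reps, min_area=config.floor_cut)
            entry["variance_components"] = {
                k: v for k, v in vars(vc).items() if k != "means"
            }
            lv = ps.locus_variance(vc.means, G.calls[scans[cond].peak], vc)
            entry["locus_variance"] = vars(lv)
        except ValueError as e:
            entry["variance_components_error"] = str(e)
        cls = report.chr1_class.reindex(G.strains)
        x = _strain_phenotype(pheno, cond, config.day).reindex(G.strains)
        eu, di = x[cls == "euploid"].dropna(), x[cls == "disome"].dropna()
        if len(eu) and len(di):
            entry["disome_test"] = ps.group_difference_tests(eu, di)
        stats["conditions"][cond] = entry
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            try:
                stats["correlations"][f"{a}|{b}"] = ps.condition_correlation(
                    _strain_phenotype(pheno, a, config.day),
                    _strain_phenotype(pheno, b, config.day),
                )
            except ValueError:
                pass
    return stats


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k != "anova"}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: cio.PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; returns the summary dict.

    Writes, under ``config.out_dir``: the filtered genotype+phenotype table,
    the ploidy table, per-condition scan and split-scan tables, the variance
    and group-test statistics, ``summary.json`` (byte-identical across
    reruns with the same config and seeds) and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("crossqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("crossqtl %s; mode=%s; seed=%d sim_seed=%d n_perm=%d",
                 __version__, config.mode, config.seed, config.sim_seed, config.n_perm)
        snps, counts, pheno, read_counts, min_markers = _load_inputs(config, out)
        cio.write_phenotypes(pheno, out / "phenotypes.tsv")
        G = _genotype_stage(snps, counts, pheno, config, min_markers)
        cio.write_genotype_phenotype_table(G, pheno, out / "genotypes_phenotypes.tsv")

        report = relative_copy_number(read_counts)
        cio.write_ploidy_report(report, out / "ploidy.tsv")

        scans, splits = _scan_stage(G, pheno, config, out)
        stats = _stats_stage(G, pheno, scans, report, config)

        meta = G.strain_meta
        summary = {
            "version": __version__,
            "mode": config.mode,
            "seeds": {"seed": config.seed, "sim_seed": config.sim_seed},
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "strains": {
                "input": int(len(meta)),
                "retained": int(meta["retained"].sum()),
                "dropped": {
                    r: int((meta["reason"] == r).sum()) for r in gt.REASON_CODES
                },
            },
            "markers": {
                "input": int(len(G.marker_meta)),
                "retained": int(G.marker_meta["retained"].sum()),
            },
            "ploidy": {
                "disomes": int((report.chr1_class == "disome").sum()),
                "euploid": int((report.chr1_class == "euploid").sum()),
                "unresolved": int((report.chr1_class == "unresolved").sum()),
            },
            "scans": {
                cond: {
                    "peak": res.peak,
                    "peak_lod": round(res.peak_lod, 6),
                    "threshold": round(res.threshold, 6),
                    "n_above_threshold": int(res.above_threshold().sum()),
                    "split_peaks": {
                        allele: {
                            "peak": s.peak,
                            "peak_lod": round(s.peak_lod, 6),
                            "threshold": round(s.threshold, 6),
                            "significant": bool(s.peak_lod > s.threshold),
                        }
                        for allele, s in splits[cond].items()
                    },
                }
                for cond, res in scans.items()
            },
            "statistics": _jsonable(stats),
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
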