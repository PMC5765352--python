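import numpy as np
import pandas as pd
import pytest

from crossqtl import (
    ChromosomeSpec,
    GenotypeMatrix,
    SimParams,
    simulate_cross,
    simulate_genotypes,
    study_like_params,
)


def genotype_matrix_from_truth(truth) -> GenotypeMatrix:
    """Error-free genotype matrix straight from simulator ground truth."""
    return GenotypeMatrix(truth.genotypes.copy(), truth.markers[["chrom", "pos"]])


@pytest.fixture
def small_params() -> SimParams:
    """Compact cross for fast unit tests: 3 chromosomes, 120 progeny."""
    return SimParams(
        n_progeny=120,
        chromosomes=[
            ChromosomeSpec("chr1", 120.0, 20),
            ChromosomeSpec("chr2", 260.0, 35),
            ChromosomeSpec("chr3", 180.0, 25),
        ],
        baseline_mean={"YPD": 25.0},
        seed=11,
    )


@pytest.fixture
def small_truth(small_params):
    return simulate_genotypes(small_params)


@pytest.fixture(scope="session")
def study_cross():
    """Full-size study-like cross shared by the slower tests."""
    params = study_like_params(seed=7)
    truth, counts, pheno = simulate_cross(params, drug_plates=True)
    return params, truth, counts, pheno


def strain_means(pheno: pd.DataFrame, condition: str, day: int = 4) -> pd.Series:
    sub = pheno[(pheno["condition"] == condition) & (pheno["day"] == day)]
    return sub.groupby("strain")["area"].mean()


def noiseless_params(**overrides) -> SimParams:
    """High depth, no sequencing error, Poisson depth: calls must be perfect."""
    base = dict(
        n_progeny=80,
        chromosomes=[ChromosomeSpec("chr1", 60.0, 8), ChromosomeSpec("chr2", 150.0, 16)],
        mean_depth=200.0,
        depth_dispersion=0.0,
        error_rate=0.0,
        seed=3,
    )
    base.update(overrides)
    return SimParams(**base)
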