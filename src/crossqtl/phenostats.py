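"""Floor-aware normalization, heritability, and distributional tests.

Growth on the harsher media is censored from below: strains that barely grow
pile up at a hard floor, so each allele subpopulation looks like a normal
distribution with its left tail collapsed.  ``quantile_normalize_floored``
reconstructs that normal by fitting location and scale to the part of the
distribution well separated from the floor and re-drawing every strain at
its own quantile.

Broad-sense heritability follows the classic segregant-means decomposition:
H^2 = 1 - sigma2_e / sigma2_s, where sigma2_s is the variance of segregant
mean phenotypes and sigma2_e = sigma2_w / n_bar is the sampling variance of
those means, with the pooled within-segregant variance sigma2_w estimated by
a one-way random-intercept model (REML).  The variance explained by one
locus is measured by zero-centering the two allele subpopulations and
comparing the pooled variance of the centered means, sigma2_ns, with
sigma2_s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "LocusVariance",
    "quantile_normalize_floored",
    "heritability",
    "locus_variance",
    "interaction_anova",
    "group_difference_tests",
    "condition_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    """Variance decomposition of segregant means for one condition (mm^4)."""

    sigma2_s: float   # variance of segregant means
    sigma2_w: float   # pooled within-segregant variance
    n_bar: float      # mean retained measurements per segregant
    sigma2_e: float   # sampling variance of the means = sigma2_w / n_bar
    H2: float         # broad-sense heritability, 1 - sigma2_e / sigma2_s
    n_strains: int    # strains entering the within-variance fit
    # the segregant means whose variance is sigma2_s; feed these to
    # locus_variance so the conservation identity holds exactly
    means: pd.Series | None = field(default=None, repr=False, compare=False)


@dataclass
class LocusVariance:
    """Genetic variance attributable to a single locus (mm^4)."""

    sigma2_ns: float          # variance of zero-centered segregant means
    explained: float          # sigma2_s - sigma2_ns
    proportion_genetic: float  # explained / (H2 * sigma2_s)
    residual_genetic: float   # sigma2_ns - sigma2_e


def quantile_normalize_floored(
    values: pd.Series,
    floor_cut: float = 5.0,
    replace_all: bool = True,
) -> pd.Series:
    """Map a floor-censored sample onto its fitted normal distribution.

    Plotting positions q_i = (rank_i - 0.5)/n (midranks for ties) are
    assigned over the whole sample; location and scale of the underlying
    normal are estimated by regressing the observed values *above*
    ``floor_cut`` on their standard-normal quantiles; every value is then
    replaced by mu + sigma * Phi^{-1}(q_i).  Rank order is preserved
    exactly.  With ``replace_all=False`` only values at or below
    ``floor_cut`` are replaced (the above-floor observations are kept
    as measured).

    Raises ``ValueError`` with fewer than 10 above-floor values or a
    non-positive fitted scale.
    """
    values = pd.Series(values).astype(float)
    n = len(values)
    above = values > floor_cut
    if int(above.sum()) < 10:
        raise ValueError(
            f"only {int(above.sum())} values above {floor_cut} mm^2; need >= 10 to fit"
        )
    q = (stats.rankdata(values.to_numpy()) - 0.5) / n
    z = stats.norm.ppf(q)
    try:
        with np.errstate(invalid="ignore"):
            slope, intercept, *_ = stats.linregress(
                z[above.to_numpy()], values[above].to_numpy()
            )
    except ValueError:
        slope = np.nan  # constant quantiles: no usable spread above the floor
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError(f"degenerate normal fit: scale {slope:.4g} <= 0")
    fitted = intercept + slope * z
    if replace_all:
        out = fitted
    else:
        out = np.where(above.to_numpy(), values.to_numpy(), np.minimum(fitted, floor_cut))
    return pd.Series(out, index=values.index, name=values.name)


def _replicate_frame(replicate_table) -> pd.DataFrame:
    if isinstance(replicate_table, pd.DataFrame):
        if not {"strain", "area"} <= set(replicate_table.columns):
            raise ValueError("replicate table needs 'strain' and 'area' columns")
        return replicate_table[["strain", "area"]]
    rows = [(s, a) for s, areas in replicate_table.items() for a in areas]
    return pd.DataFrame(rows, columns=["strain", "area"])


def _reml_within_variance(df: pd.DataFrame) -> float:
    """Residual variance of a one-way random-intercept model fit by REML."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df["area"].to_numpy(),
            np.ones((len(df), 1)),
            groups=df["strain"].to_numpy(),
        )
        return float(model.fit(reml=True).scale)


def _moments_within_variance(df: pd.DataFrame) -> float:
    """Pooled within-strain variance: sum of squares about strain means over sum (n_s - 1)."""
    g = df.groupby("strain")["area"]
    ss = ((df["area"] - g.transform("mean")) ** 2).sum()
    dof = (g.size() - 1).sum()
    return float(ss / dof)


def heritability(
    replicate_table,
    min_area: float = 5.0,
    min_reps: int = 2,
    method: str = "reml",
    strain_means: pd.Series | None = None,
) -> VarianceComponents:
    """Broad-sense heritability from replicate patch areas.

    The floor filter applies to the *within*-variance fit only: measurements
    at or below ``min_area`` are discarded there, as are strains left with
    fewer than ``min_reps`` such measurements, and ``sigma2_w`` comes from a
    one-way random-intercept REML fit on the survivors (``method="moments"``
    substitutes the closed-form pooled within-strain variance, identical for
    balanced data).  ``sigma2_s`` is the variance of the population of
    segregant means: each strain's plain replicate mean, or ``strain_means``
    (e.g. quantile-normalized means) when provided.

    ``replicate_table`` is a mapping strain -> areas or a long DataFrame
    with 'strain' and 'area' columns.
    """
    full = _replicate_frame(replicate_table)
    df = full[full["area"] > min_area]
    sizes = df.groupby("strain")["area"].size()
    keep = sizes.index[sizes >= min_reps]
    df = df[df["strain"].isin(keep)]
    if df["strain"].nunique() < 2:
        raise ValueError("fewer than 2 strains pass the heritability filters")

    if df.groupby("strain")["area"].var(ddof=1).fillna(0).max() == 0:
        sigma2_w = 0.0  # replicates identical within every strain; REML degenerate
    elif method == "reml":
        sigma2_w = _reml_within_variance(df)
    elif method == "moments":
        sigma2_w = _moments_within_variance(df)
    else:
        raise ValueError(f"unknown method {method!r}")

    n_bar = float(df.groupby("strain").size().mean())
    sigma2_e = sigma2_w / n_bar
    if strain_means is not None:
        means = pd.Series(strain_means).dropna()
    else:
        means = full.groupby("strain")["area"].mean()
    sigma2_s = float(means.var(ddof=1))
    if sigma2_s == 0:
        raise ValueError("zero variance of segregant means; H2 undefined")
    return VarianceComponents(
        sigma2_s=sigma2_s,
        sigma2_w=sigma2_w,
        n_bar=n_bar,
        sigma2_e=sigma2_e,
        H2=1.0 - sigma2_e / sigma2_s,
        n_strains=int(df["strain"].nunique()),
        means=means,
    )


def locus_variance(
    segregant_means: pd.Series, alleles: pd.Series, vc: VarianceComponents
) -> LocusVariance:
    """Genetic variance explained by one locus via zero-centered subpopulations.

    Each allele subpopulation's mean phenotype is subtracted from its
    members; ``sigma2_ns`` is the variance of the pooled centered means and
    ``explained = sigma2_s - sigma2_ns`` the variance the locus accounts
    for.  Under the null (allele independent of phenotype) ``explained`` is
    near zero and may come out slightly negative; it is reported as-is, with
    a warning.
    """
    alleles = alleles.reindex(segregant_means.index)
    keep = alleles.isin(["P1", "P2"]) & segregant_means.notna()
    if not keep.any():
        raise ValueError("no strains with both an allele call and a phenotype")
    means = segregant_means[keep]
    alleles = alleles[keep]
    for a in ("P1", "P2"):
        if not (alleles == a).any():
            raise ValueError(f"allele class {a} is empty")
    centered = means - alleles.map(means.groupby(alleles).mean())
    sigma2_ns = float(centered.var(ddof=1))
    explained = vc.sigma2_s - sigma2_ns
    if explained < 0:
        warnings.warn(
            f"negative explained variance ({explained:.4g} mm^4); "
            "allele is likely independent of the phenotype",
            stacklevel=2,
        )
    return LocusVariance(
        sigma2_ns=sigma2_ns,
        explained=explained,
        proportion_genetic=explained / (vc.H2 * vc.sigma2_s),
        residual_genetic=sigma2_ns - vc.sigma2_e,
    )


def interaction_anova(area, allele, additive_present) -> dict:
    """Two-factor fixed-effects ANOVA with interaction (Type II sums of squares).

    Tests whether the effect of the locus allele on patch area depends on
    the presence of the medium additive.  Returns the interaction term's F
    statistic and p-value.  Raises if any of the four factor cells is empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "area": np.asarray(area, dtype=float),
            "allele": np.asarray(allele, dtype=object),
            "additive": np.asarray(additive_present, dtype=object),
        }
    ).dropna()
    cells = df.groupby(["allele", "additive"], observed=True).size()
    for a in df["allele"].unique():
        for b in df["additive"].unique():
            if (a, b) not in cells.index:
                raise ValueError(f"empty factor cell: allele={a!r}, additive={b!r}")
    fit = smf.ols("area ~ C(allele) * C(additive)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    row = table.loc["C(allele):C(additive)"]
    return {"F": float(row["F"]), "p": float(row["PR(>F)"]), "anova": table}


def group_difference_tests(x, y) -> dict:
    """Mann-Whitney U comparison of two groups of patch areas.

    Returns the U statistic, the two-sided p-value (exact enumeration when
    both groups are small and tie-free, otherwise the tie-corrected normal
    approximation), and the raw difference of means in mm^2.  Multiple-
    testing correction across conditions is the caller's responsibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "mean_difference": float(x.mean() - y.mean()),
        "n_x": int(x.size),
        "n_y": int(y.size),
    }


def condition_correlation(a: pd.Series, b: pd.Series) -> float:
    """Pearson correlation of per-strain means between two conditions.

    Computed over strains present (non-missing) in both; requires at least
    three complete pairs and non-degenerate variance in each vector.
    """
    df = pd.concat([pd.Series(a), pd.Series(b)], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(df)}")
    va, vb = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    return float(stats.pearsonr(va, vb).statistic)
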