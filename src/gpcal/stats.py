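"""Group-level statistics for genotype and treatment comparisons.

The testing policy mirrors standard practice for these cohorts: a
Shapiro-Wilk gate decides between parametric and nonparametric families;
unpaired two-group comparisons use the two-sided Mann-Whitney U (exact null
for small samples, tie-corrected normal approximation otherwise) and report
medians with distribution-free 95% CIs; distribution-shape comparisons use
the two-sample Kolmogorov-Smirnov test with ECDF tables and 25/75
percentiles; genotype x treatment designs use a two-way ANOVA (Type II sums
of squares) with cell means +/- SE. Alpha is 0.05, two-sided, throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "normality_gate",
    "compare_unpaired",
    "ecdf_compare",
    "factorial_compare",
    "median_ci",
]

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of one metric's group comparison, with per-group summaries."""

    metric: str
    groups: tuple[str, ...]
    n: dict[str, int]
    test: str  # Mann-Whitney | Kolmogorov-Smirnov | two-way ANOVA
    statistic: float
    p_value: float
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    percentiles_25_75: dict[str, tuple[float, float]] = field(default_factory=dict)
    ecdf: dict[str, pd.DataFrame] = field(default_factory=dict)
    effects: pd.DataFrame | None = None  # ANOVA table when applicable
    degenerate: bool = False


def _clean(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[np.isfinite(arr)]


def normality_gate(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> tuple[str, dict[str, float]]:
    """Choose the test family from per-group Shapiro-Wilk normality tests.

    Returns ``("parametric" | "nonparametric", per-group p-values)``; the
    family is nonparametric as soon as any group rejects normality at
    ``alpha``. Groups with n < 3 or zero variance cannot be assessed and
    force the nonparametric branch (with a warning).
    """
    pvals: dict[str, float] = {}
    decision = "parametric"
    for name, values in samples.items():
        x = _clean(values)
        if x.size < 3:
            log.warning("group %s has n=%d < 3: defaulting to nonparametric", name, x.size)
            pvals[name] = np.nan
            decision = "nonparametric"
            continue
        if np.ptp(x) == 0:
            log.warning("group %s is constant-valued: defaulting to nonparametric", name)
            pvals[name] = np.nan
            decision = "nonparametric"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sps.shapiro(x).pvalue)
        pvals[name] = p
        if p < alpha:
            decision = "nonparametric"
    return decision, pvals


def median_ci(x: np.ndarray, coverage: float = 0.95) -> tuple[float, float, float]:
    """Distribution-free CI for the median from order statistics.

    Uses the binomial argument: (x_(l), x_(u)) with u = n - l + 1 covers the
    median with probability 1 - 2 * BinomCDF(l - 1; n, 1/2); l is the largest
    rank achieving at least the requested coverage. Returns (lo, hi,
    achieved coverage); for tiny n the full range is returned.
    """
    x = np.sort(_clean(x))
    n = x.size
    if n == 0:
        return (np.nan, np.nan, 0.0)
    if n == 1:
        return (x[0], x[0], 0.0)
    alpha = (1.0 - coverage) / 2.0
    cdf = sps.binom.cdf(np.arange(n), n, 0.5)
    ok = np.flatnonzero(cdf <= alpha)  # cdf[l-1] <= alpha/2
    l = int(ok[-1] + 1) if ok.size else 0
    if l < 1:
        return (x[0], x[-1], float(1.0 - 2.0 * cdf[0] + sps.binom.pmf(0, n, 0.5)))
    u = n - l + 1
    achieved = float(1.0 - 2.0 * cdf[l - 1])
    return (float(x[l - 1]), float(x[u - 1]), achieved)


def _median_summary(x: np.ndarray) -> dict[str, float]:
    lo, hi, cov = median_ci(x)
    return {
        "median": float(np.median(x)),
        "ci_low": lo,
        "ci_high": hi,
        "ci_coverage": cov,
        "mean": float(np.mean(x)),
        "se": float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan,
    }


def compare_unpaired(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
    metric: str = "",
    exact_max_n: int = 8,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two unpaired samples.

    The exact null distribution is used when the smaller sample has at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction. Summaries
    are medians with distribution-free 95% CIs, following the nonparametric
    family.
    """
    xa, xb = _clean(a), _clean(b)
    if xa.size < 1 or xb.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([xa, xb])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        res_stat = float(xa.size * xb.size / 2.0)
        return GroupComparison(
            metric=metric, groups=labels, n={labels[0]: xa.size, labels[1]: xb.size},
            test="Mann-Whitney", statistic=res_stat, p_value=1.0,
            summaries={labels[0]: _median_summary(xa), labels[1]: _median_summary(xb)},
            percentiles_25_75={
                labels[0]: tuple(np.percentile(xa, [25, 75])),
                labels[1]: tuple(np.percentile(xb, [25, 75])),
            },
            degenerate=True,
        )
    method = "exact" if (min(xa.size, xb.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return GroupComparison(
        metric=metric,
        groups=labels,
        n={labels[0]: xa.size, labels[1]: xb.size},
        test="Mann-Whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        summaries={labels[0]: _median_summary(xa), labels[1]: _median_summary(xb)},
        percentiles_25_75={
            labels[0]: tuple(np.percentile(xa, [25, 75])),
            labels[1]: tuple(np.percentile(xb, [25, 75])),
        },
    )


def _ecdf_table(x: np.ndarray) -> pd.DataFrame:
    xs = np.sort(x)
    return pd.DataFrame({"value": xs, "cum_fraction": np.arange(1, xs.size + 1) / xs.size})


def ecdf_compare(
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str] = ("A", "B"),
    metric: str = "",
) -> GroupComparison:
    """Two-sample Kolmogorov-Smirnov comparison of cumulative distributions.

    D = sup |ECDF_a - ECDF_b| with the asymptotic two-sided p-value; the
    ECDF tables and 25/75 percentiles (linear interpolation between closest
    ranks) are returned for cumulative-frequency plots.
    """
    xa, xb = _clean(a), _clean(b)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("both groups need at least two observations")
    res = sps.ks_2samp(xa, xb, alternative="two-sided", method="asymp")
    return GroupComparison(
        metric=metric,
        groups=labels,
        n={labels[0]: xa.size, labels[1]: xb.size},
        test="Kolmogorov-Smirnov",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries={labels[0]: _median_summary(xa), labels[1]: _median_summary(xb)},
        percentiles_25_75={
            labels[0]: tuple(np.percentile(xa, [25, 75])),
            labels[1]: tuple(np.percentile(xb, [25, 75])),
        },
        ecdf={labels[0]: _ecdf_table(xa), labels[1]: _ecdf_table(xb)},
    )


def factorial_compare(
    values: np.ndarray,
    genotype: np.ndarray,
    treatment: np.ndarray,
    metric: str = "",
) -> GroupComparison:
    """Two-way ANOVA (genotype x treatment, Type II SS) with cell means +/- SE."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "genotype": np.asarray(genotype), "treatment": np.asarray(treatment)}
    ).dropna()
    counts = df.groupby(["genotype", "treatment"], observed=True).size()
    genotypes = df["genotype"].unique()
    treatments = df["treatment"].unique()
    if len(genotypes) < 2 or len(treatments) < 2:
        raise ValueError("need at least 2 levels per factor")
    for g in genotypes:
        for t in treatments:
            if counts.get((g, t), 0) < 2:
                raise ValueError(f"design cell ({g}, {t}) has fewer than 2 observations")

    model = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
    if np.allclose(np.ptp(df["value"].to_numpy()), 0.0):
        # all observations identical: F ratios are 0/0; report the degenerate limit
        table = pd.DataFrame(
            {"F": [0.0, 0.0, 0.0], "PR(>F)": [1.0, 1.0, 1.0]},
            index=["C(genotype)", "C(treatment)", "C(genotype):C(treatment)"],
        )
    else:
        table = sm.stats.anova_lm(model, typ=2)

    cell_stats = df.groupby(["genotype", "treatment"], observed=True)["value"].agg(
        ["mean", "sem", "count"]
    )
    summaries = {
        f"{g}:{t}": {
            "mean": float(cell_stats.loc[(g, t), "mean"]),
            "se": float(cell_stats.loc[(g, t), "sem"]),
            "n": int(cell_stats.loc[(g, t), "count"]),
        }
        for g in genotypes
        for t in treatments
    }
    interaction = "C(genotype):C(treatment)"
    return GroupComparison(
        metric=metric,
        groups=tuple(str(g) for g in genotypes),
        n={str(g): int(df[df["genotype"] == g].shape[0]) for g in genotypes},
        test="two-way ANOVA",
        statistic=float(table.loc[interaction, "F"]),
        p_value=float(table.loc[interaction, "PR(>F)"]),
        summaries=summaries,
        effects=table,
    )
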