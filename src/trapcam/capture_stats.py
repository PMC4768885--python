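"""Statistical analysis of capture counts and detection series.

Covers: per-column Mean±SD summaries of replicate capture tables; one-way
ANOVA comparing two treatments on ln(x+1)-transformed counts; two-way ANOVA
(bait x surface, with interaction) of log-transformed detection counts;
Fisher's unadjusted Least Significant Difference post hoc; and a one-sample
Kolmogorov-Smirnov normality check of the transformed response against a
normal law with the observed mean and standard deviation.

Count data are transformed as ln(x + 1): the offset admits zero counts and
stabilises the variance of overdispersed counts, and F statistics are
invariant to the base of the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "log1_transform",
    "summarize",
    "format_mean_sd",
    "one_way_anova",
    "two_way_anova",
    "fisher_lsd",
    "ks_normality",
    "LsdResult",
    "KsResult",
]


def log1_transform(counts) -> np.ndarray:
    """Natural log of (count + 1); rejects negative input."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log1p(x)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Column means and sample standard deviations (n-1 denominator).

    Non-numeric columns (dates, labels) are ignored.  Returns a frame with
    rows ``mean``, ``sd`` and (for reports) 1-decimal rounded versions
    ``mean_1dp``, ``sd_1dp``; the unrounded values are retained.
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("need at least 2 rows for a sample SD")
    mean = numeric.mean()
    sd = numeric.std(ddof=1)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "mean_1dp": mean.round(1), "sd_1dp": sd.round(1)}
    ).T


def format_mean_sd(summary: pd.DataFrame, column: str) -> str:
    """Render one column's summary as the conventional ``mean±SD`` string."""
    return f"{summary.loc['mean_1dp', column]:.1f}±{summary.loc['sd_1dp', column]:.1f}"


def one_way_anova(group_a, group_b) -> pd.DataFrame:
    """Two-group one-way ANOVA by the between/within decomposition.

    Returns the table with rows ``treatment`` and ``residual`` and columns
    ``df``, ``sum_sq``, ``mean_sq``, ``F``, ``p``.  F has (1, n_a+n_b-2)
    degrees of freedom and equals the square of the pooled two-sample t.
    Zero residual variance yields an infinite F (flagged by the value
    itself), not an exception.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    grand = np.concatenate([a, b]).mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_b, df_w = 1, len(a) + len(b) - 2
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    return pd.DataFrame(
        {
            "df": [df_b, df_w],
            "sum_sq": [ss_between, ss_within],
            "mean_sq": [ms_b, ms_w],
            "F": [f, np.nan],
            "p": [p, np.nan],
        },
        index=["treatment", "residual"],
    )


def two_way_anova(
    data: pd.DataFrame,
    response: str = "response",
    factor_a: str = "bait",
    factor_b: str = "surface",
    typ: int = 1,
) -> pd.DataFrame:
    """Two-factor ANOVA with interaction.

    ``typ=1`` (sequential sums of squares) is exact on balanced designs;
    ``typ=2`` (marginal) is the appropriate choice for unbalanced data such
    as designs with missing camera-days.  Row index: the two factors, their
    interaction, and ``Residual``; achieved degrees of freedom are reported
    as-is.
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    for factor in (factor_a, factor_b):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    if data[response].max() == data[response].min():
        # no variance to partition: report zero SS and undefined F
        levels_a = data[factor_a].nunique()
        levels_b = data[factor_b].nunique()
        dfs = [levels_a - 1, levels_b - 1, (levels_a - 1) * (levels_b - 1)]
        dfs.append(len(data) - 1 - sum(dfs))
        return pd.DataFrame(
            {
                "df": dfs,
                "sum_sq": 0.0,
                "mean_sq": 0.0,
                "F": [np.nan] * 4,
                "p": [np.nan] * 4,
            },
            index=[factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"],
        )
    model = smf.ols(
        f"{response} ~ C({factor_a}) * C({factor_b})", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    out = table.rename(
        columns={"PR(>F)": "p"},
        index={
            f"C({factor_a})": factor_a,
            f"C({factor_b})": factor_b,
            f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
        },
    )
    out["mean_sq"] = out["sum_sq"] / out["df"]
    return out[["df", "sum_sq", "mean_sq", "F", "p"]]


@dataclass
class LsdResult:
    """Pairwise comparisons under a common least-significant difference."""

    alpha: float
    lsd: float
    comparisons: pd.DataFrame  # columns: group_1, group_2, mean_diff, significant


def fisher_lsd(
    cell_means: dict[str, float],
    n_per_cell: int,
    residual_ms: float,
    residual_df: int,
    alpha: float = 0.05,
) -> LsdResult:
    """Fisher's LSD test over all pairs of cell means.

    LSD = t(1 - alpha/2, residual_df) * sqrt(2 * residual_ms / n); a pair
    is significant when |mean difference| exceeds the LSD.  By convention
    no multiplicity adjustment is applied.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if residual_ms <= 0:
        raise ValueError("residual mean square must be positive")
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")
    t_crit = stats.t.ppf(1 - alpha / 2, residual_df)
    lsd = t_crit * np.sqrt(2 * residual_ms / n_per_cell)
    labels = list(cell_means)
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            diff = cell_means[g1] - cell_means[g2]
            rows.append((g1, g2, diff, bool(abs(diff) > lsd)))
    comparisons = pd.DataFrame(
        rows, columns=["group_1", "group_2", "mean_diff", "significant"]
    )
    return LsdResult(alpha=alpha, lsd=float(lsd), comparisons=comparisons)


@dataclass
class KsResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal."""

    d: float
    p: float
    mean: float
    sd: float


def ks_normality(
    values, mean: float | None = None, sd: float | None = None
) -> KsResult:
    """KS distance of the sample from a normal law.

    By default the reference normal uses the sample mean and SD (n-1
    denominator); explicit ``mean``/``sd`` override the estimation.  The
    p-value comes from the asymptotic Kolmogorov distribution with no
    small-sample or estimated-parameter correction.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    mu = x.mean() if mean is None else mean
    sigma = x.std(ddof=1) if sd is None else sd
    if sigma <= 0:
        raise ValueError("sample standard deviation must be positive")
    cdf = stats.norm.cdf(x, loc=mu, scale=sigma)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    d = float(max(upper.max(), lower.max()))
    p = float(special.kolmogorov(np.sqrt(n) * d))
    return KsResult(d=d, p=p, mean=float(mu), sd=float(sigma))
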