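"""Closed-form statistics for demographics tables and voxel-wise building blocks.

Implements the small set of classical tests used to characterise a
case-control cohort (two-sample t, one-way ANOVA, chi-square independence)
both from raw data and from published ``mean +/- SD`` summaries, plus the
correlation and multiple-testing primitives (Pearson r, partial
correlation, Benjamini-Hochberg FDR) that the voxel-wise stages reuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "two_sample_t",
    "oneway_anova_from_summaries",
    "oneway_anova",
    "chi_square_independence",
    "pearson_r",
    "partial_correlation",
    "bh_fdr",
    "demographics_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and sample SD (n-1 denominator) of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_data(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str


def two_sample_t(
    a: GroupSummary | np.ndarray,
    b: GroupSummary | np.ndarray,
    pooled: bool = True,
) -> TestResult:
    """Two-sample t-test from summaries or raw vectors.

    The pooled (Student) variant uses the pooled variance with
    ``n1 + n2 - 2`` degrees of freedom; the unpooled variant uses the Welch
    statistic with Welch-Satterthwaite df.  The sign convention is
    ``(a.mean - b.mean) / SE``.  Raw-data inputs are summarised first, so
    the two call styles agree exactly.
    """
    if not isinstance(a, GroupSummary):
        a = GroupSummary.from_data(a)
    if not isinstance(b, GroupSummary):
        b = GroupSummary.from_data(b)
    diff = a.mean - b.mean
    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, "t (pooled)")
        raise ValueError("zero variance in both groups with unequal means")
    va, vb = a.sd**2, b.sd**2
    if pooled:
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        method = "t (pooled)"
    else:
        sea2, seb2 = va / a.n, vb / b.n
        se = np.sqrt(sea2 + seb2)
        df = (sea2 + seb2) ** 2 / (
            sea2**2 / (a.n - 1) + seb2**2 / (b.n - 1)
        )
        method = "t (Welch)"
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), method)


def oneway_anova_from_summaries(groups: list[GroupSummary]) -> TestResult:
    """One-way ANOVA F from per-group (n, mean, sd) summaries.

    Between-group SS is taken about the grand (n-weighted) mean; within-group
    MS pools the group variances.  Identical to the raw-data ANOVA on any
    data reproducing the summaries.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    n_total = ns.sum()
    k = len(groups)
    grand = float(np.sum(ns * means) / n_total)
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_b, df_w = float(k - 1), float(n_total - k)
    ms_within = ss_within / df_w
    if ms_within == 0.0:
        raise ValueError("zero within-group variance")
    f = (ss_between / df_b) / ms_within
    p = sps.f.sf(f, df_b, df_w)
    return TestResult(float(f), (df_b, df_w), float(p), "one-way ANOVA")


def oneway_anova(samples: list[np.ndarray]) -> TestResult:
    """Raw-data one-way ANOVA; agrees exactly with the summary overload."""
    return oneway_anova_from_summaries([GroupSummary.from_data(x) for x in samples])


def chi_square_independence(table: np.ndarray) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = float((obs.shape[0] - 1) * (obs.shape[1] - 1))
    p = sps.chi2.sf(stat, df)
    return TestResult(stat, df, float(p), "chi-square")


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial correlation of ``x`` and ``y`` given covariate columns.

    Both variables are residualised on the covariate design (with an
    intercept) by least squares; the Pearson correlation of the residuals is
    returned with a p-value on ``n - 2 - n_covariates`` degrees of freedom.
    With no covariates this reduces exactly to :func:`pearson_r`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        return pearson_r(x, y)
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] != len(x):
        z = z.T
    n, q = z.shape
    if n != len(x) or len(x) != len(y):
        raise ValueError("misaligned inputs")
    if n < q + 3:
        raise ValueError("need at least n_covariates + 3 observations")
    design = np.column_stack([np.ones(n), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which added columns are linear combinations of earlier ones
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(
                design[:, :j]
            ):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient covariate design; collinear columns {bad}")
    coef_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.std(rx) <= 1e-10 * (np.std(x) + 1.0) or np.std(ry) <= 1e-10 * (np.std(y) + 1.0):
        raise ValueError("residual variance is zero (variable collinear with covariates)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    if df <= 0:
        raise ValueError("not enough degrees of freedom")
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(rejected, p_adjusted)``.  Adjusted p-values are monotone in
    the sorted order and the rejection set is a prefix of that order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    rejected = adjusted <= q
    return rejected, adjusted


def demographics_table(cohort, group_order: list[str] | None = None):
    """Summarise a cohort DataFrame the way case-control papers tabulate it.

    Continuous variables get per-group ``mean +/- SD`` plus a one-way ANOVA
    (>=3 groups) or pooled t-test (2 groups); sex gets a chi-square test.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    groups = group_order or sorted(cohort["group"].unique())
    rows = []
    # sex counts
    counts = np.array(
        [
            [
                int(((cohort["group"] == g) & (cohort["sex"] == s)).sum())
                for g in groups
            ]
            for s in ("M", "F")
        ]
    )
    chi = chi_square_independence(counts)
    rows.append(
        {
            "characteristic": "sex (M/F)",
            **{
                g: f"{counts[0, i]}/{counts[1, i]}" for i, g in enumerate(groups)
            },
            "statistic": chi.statistic,
            "p_value": chi.p_value,
            "method": chi.method,
        }
    )
    for col in ("age", "education", "hamd17", "hama14"):
        if col not in cohort:
            continue
        present = [g for g in groups if cohort.loc[cohort["group"] == g, col].notna().all()
                   and (cohort["group"] == g).sum() >= 2]
        samples = [cohort.loc[cohort["group"] == g, col].to_numpy(float) for g in present]
        if len(samples) < 2:
            continue
        if len(samples) == 2:
            res = two_sample_t(samples[0], samples[1])
        else:
            res = oneway_anova(samples)
        row = {"characteristic": col}
        for g, s in zip(present, samples):
            row[g] = f"{np.mean(s):.2f}±{np.std(s, ddof=1):.2f}"
        row.update(statistic=res.statistic, p_value=res.p_value, method=res.method)
        rows.append(row)
    return pd.DataFrame(rows)
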