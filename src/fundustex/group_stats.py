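"""Nonparametric group comparison: two-sample Kolmogorov-Smirnov,
Wilcoxon-Mann-Whitney rank sum, a Monte-Carlo Lilliefors normality
check, and per-feature group summary tables.

All tests are two-sided.  No multiple-comparison correction is applied
by default; an optional Benjamini-Hochberg adjustment is provided for
users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "ks_two_sample",
    "rank_sum",
    "lilliefors",
    "summarize_groups",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int = 0


def _validate_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def _ks_asymptotic_p(d: float, en: float) -> float:
    """Asymptotic two-sample KS p-value with small-sample correction."""
    lam = max((np.sqrt(en) + 0.12 + 0.11 / np.sqrt(en)) * d, 0.0)
    if lam == 0.0:
        return 1.0
    j = np.arange(1, 102, dtype=np.float64)
    p = 2.0 * np.sum((-1.0) ** (j - 1) * np.exp(-2.0 * (j * lam) ** 2))
    return float(min(max(p, 0.0), 1.0))


def ks_two_sample(xs, ys) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    Statistic: supremum of |F_x - F_y| over the pooled sample points;
    p-value from the asymptotic Kolmogorov distribution with effective
    sample size n1*n2/(n1+n2).
    """
    xs = _validate_sample(xs, "xs")
    ys = _validate_sample(ys, "ys")
    pooled = np.concatenate([xs, ys])
    xs_sorted = np.sort(xs)
    ys_sorted = np.sort(ys)
    fx = np.searchsorted(xs_sorted, pooled, side="right") / xs.size
    fy = np.searchsorted(ys_sorted, pooled, side="right") / ys.size
    d = float(np.max(np.abs(fx - fy)))
    en = xs.size * ys.size / (xs.size + ys.size)
    return TestResult(d, _ks_asymptotic_p(d, en), "ks_two_sample", xs.size, ys.size)


def rank_sum(xs, ys) -> TestResult:
    """Wilcoxon-Mann-Whitney rank-sum test with midrank ties.

    Statistic: Mann-Whitney U of the first sample.  Two-sided p-value by
    normal approximation with tie and continuity corrections.
    """
    xs = _validate_sample(xs, "xs")
    ys = _validate_sample(ys, "ys")
    n1, n2 = xs.size, ys.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([xs, ys]), method="average")
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(np.concatenate([xs, ys]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # every observation tied: no evidence against the null
        return TestResult(float(u1), 1.0, "rank_sum", n1, n2)
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return TestResult(float(u1), p, "rank_sum", n1, n2)


def _lilliefors_statistic(xs: np.ndarray) -> float:
    """KS distance between the sample and Normal(mean, sd) fitted to it."""
    n = xs.size
    z = np.sort((xs - xs.mean()) / xs.std(ddof=1))
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def lilliefors(xs, n_mc: int = 2000, seed: int = 0) -> TestResult:
    """Normality test with estimated mean and SD, Monte-Carlo p-value.

    The null distribution of the statistic is simulated with ``n_mc``
    standard-normal samples of the same size drawn from a seeded
    generator, so p-values are reproducible for a fixed seed.
    """
    xs = _validate_sample(xs, "xs")
    if xs.size < 4:
        raise ValueError("lilliefors requires n >= 4")
    if xs.std(ddof=1) == 0:
        raise ValueError("sample has zero variance")
    d_obs = _lilliefors_statistic(xs)
    rng = np.random.default_rng(seed)
    null = rng.standard_normal((n_mc, xs.size))
    d_null = np.array([_lilliefors_statistic(row) for row in null])
    p = (1.0 + np.sum(d_null >= d_obs)) / (n_mc + 1.0)
    return TestResult(d_obs, float(p), "lilliefors", xs.size)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def summarize_groups(
    table: pd.DataFrame,
    feature_cols: list[str] | None = None,
    group_col: str = "group",
    adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature group means/SDs and pairwise KS comparisons.

    Parameters
    ----------
    table : DataFrame
        One row per image with a group label column and numeric feature
        columns.
    feature_cols : list of str, optional
        Defaults to every numeric column except the group column.
    adjust : bool
        Apply Benjamini-Hochberg to the p-values (default False: no
        multiple-comparison correction).

    Returns
    -------
    (summary, tests)
        ``summary``: rows (feature, group, mean, sd) with sample SD
        (n-1 denominator). ``tests``: rows (feature, group_a, group_b,
        statistic, p_value).
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if feature_cols is None:
        feature_cols = [
            c
            for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    for g in groups:
        if (table[group_col] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members; SD undefined")

    summary_rows = []
    test_rows = []
    for feat in feature_cols:
        by_group = {g: table.loc[table[group_col] == g, feat].to_numpy() for g in groups}
        for g in groups:
            vals = by_group[g]
            summary_rows.append(
                {
                    "feature": feat,
                    "group": g,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                    "n": int(vals.size),
                }
            )
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                res = ks_two_sample(by_group[ga], by_group[gb])
                test_rows.append(
                    {
                        "feature": feat,
                        "group_a": ga,
                        "group_b": gb,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    tests = pd.DataFrame(test_rows)
    if adjust and not tests.empty:
        tests["p_adjusted"] = benjamini_hochberg(tests["p_value"].to_numpy())
    return pd.DataFrame(summary_rows), tests
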