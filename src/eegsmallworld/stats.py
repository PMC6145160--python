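"""Group-comparison statistics with SPSS-compatible reporting.

The Mann-Whitney U test reports U = min(U_a, U_b), the companion
rank-sum W of the group attaining that minimum (SPSS's "Wilcoxon W",
which equals U + n_min*(n_min+1)/2), and a two-sided p from the normal
approximation with tie-corrected variance and *no* continuity
correction — the convention that reproduces SPSS's printed asymptotic
p-values. An exact-enumeration p is available for small samples
without ties.

Also provided: pooled-variance independent t-test (including a
summary-statistic form so published means/SDs can be audited), Pearson
correlation with a t-distribution p, and the Shapiro-Wilk normality
screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class TestResult:
    statistic_name: str  # U | t | r | W_shapiro
    statistic: float
    p_two_sided: float
    companion: float | None = None  # SPSS Wilcoxon W for U-tests
    n1: int | None = None
    n2: int | None = None
    grid_parameter: float | None = None
    metric: str | None = None


@dataclass
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int
    which_metric: str | None = None
    cohort: str | None = None


def _tie_corrected_sd(all_values: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return float(np.sqrt(var))


def mwu_p_asymptotic(u: float, n1: int, n2: int, tie_term_sd: float | None = None) -> float:
    """Two-sided normal-approximation p for a Mann-Whitney U (the min of
    the two U statistics), without continuity correction."""
    mu = n1 * n2 / 2.0
    sd = tie_term_sd if tie_term_sd is not None else float(np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0))
    if sd == 0:
        return 1.0
    z = (u - mu) / sd
    return float(min(2.0 * sps.norm.cdf(-abs(z)), 1.0))


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "asymptotic",
    grid_parameter: float | None = None,
    metric: str | None = None,
) -> TestResult:
    """Mann-Whitney U test between two independent samples.

    ``method`` is "asymptotic" (tie-corrected normal approximation, no
    continuity correction) or "exact" (full-enumeration distribution,
    small samples without ties).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("empty group")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(np.concatenate([a, b]))  # midranks for ties
    r_a = float(ranks[:n1].sum())
    r_b = float(ranks[n1:].sum())
    u_a = r_a - n1 * (n1 + 1) / 2.0
    u_b = r_b - n2 * (n2 + 1) / 2.0
    if u_a <= u_b:
        u, w = u_a, r_a
    else:
        u, w = u_b, r_b
    if method == "asymptotic":
        sd = _tie_corrected_sd(np.concatenate([a, b]), n1, n2)
        p = mwu_p_asymptotic(u, n1, n2, tie_term_sd=sd)
    elif method == "exact":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        raise StatsError(f"unknown method {method!r}")
    return TestResult("U", float(u), p, companion=w, n1=n1, n2=n2,
                      grid_parameter=grid_parameter, metric=metric)


def sweep_tests(
    metrics_a: Mapping[str, Mapping[float, Sequence[float]]],
    metrics_b: Mapping[str, Mapping[float, Sequence[float]]],
    method: str = "asymptotic",
) -> tuple[list[TestResult], dict[str, float]]:
    """One U-test per grid point per metric.

    ``metrics_a``/``metrics_b`` map metric name (e.g. "C", "L") to
    {grid parameter: per-subject values}. Returns all test results plus,
    per metric, the grid parameter attaining the minimum p.
    """
    if set(metrics_a) != set(metrics_b):
        raise StatsError("metric sets differ between groups")
    results: list[TestResult] = []
    argmin_p: dict[str, float] = {}
    for metric in sorted(metrics_a):
        grid_a, grid_b = metrics_a[metric], metrics_b[metric]
        if set(grid_a) != set(grid_b):
            raise StatsError(f"grid mismatch for metric {metric!r}")
        best_p, best_param = np.inf, None
        for param in sorted(grid_a):
            res = mann_whitney_u(grid_a[param], grid_b[param], method=method,
                                 grid_parameter=float(param), metric=metric)
            results.append(res)
            if res.p_two_sided < best_p:
                best_p, best_param = res.p_two_sided, float(param)
        argmin_p[metric] = best_param
    return results, argmin_p


def t_from_summary(mean_a: float, sd_a: float, n_a: int,
                   mean_b: float, sd_b: float, n_b: int) -> TestResult:
    """Pooled-variance two-sided independent t-test from summary
    statistics (means, SDs, group sizes)."""
    if n_a < 2 or n_b < 2:
        raise StatsError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise StatsError("SDs must be positive")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("t", float(t), p, n1=n_a, n2=n_b)


def independent_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need n >= 2 per group")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult("t", float(t), float(p), n1=a.size, n2=b.size)


def pearson_correlation(
    x: Sequence[float],
    y: Sequence[float],
    which_metric: str | None = None,
    cohort: str | None = None,
) -> CorrelationResult:
    """Pearson product-moment r with two-sided t-distribution p on n-2
    degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("length mismatch")
    if x.size < 3:
        raise StatsError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size),
                             which_metric=which_metric, cohort=cohort)


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test; annotates, never gates, the
    downstream nonparametric comparisons."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise StatsError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.std(v) == 0:
        raise StatsError("constant sample")
    w, p = sps.shapiro(v)
    return TestResult("W_shapiro", float(w), float(p), n1=v.size)
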