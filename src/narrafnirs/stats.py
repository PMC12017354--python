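"""Normality-gated univariate group comparisons, effect sizes and power.

The comparison recipe mirrors common practice in small clinical samples:
Shapiro-Wilk decides between the independent-samples t-test (Welch) and
the Mann-Whitney U test for continuous variables; categorical variables
get Pearson's chi-square; effect sizes are |Cohen's d|, |Cliff's delta|
or |Cohen's h| to match the test family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .datatypes import ConfigurationError, InputError


@dataclass
class ComparisonResult:
    variable: str
    test: str            # "t" | "mann-whitney" | "chi-square"
    statistic: float
    p_value: float
    effect_size_name: str
    effect_size: float


@dataclass
class CorrelationResult:
    method: str          # "pearson" | "spearman" | "none"
    r: float
    p_value: float


def cliffs_delta(x: Sequence[float], y: Sequence[float]) -> float:
    """Dominance effect size: P(x > y) - P(x < y) over all pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InputError("cliffs_delta needs non-empty samples")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardized mean difference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine-transformed difference of two proportions."""
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise InputError("proportions must lie in [0, 1]")
    return float(2 * math.asin(math.sqrt(p1)) - 2 * math.asin(math.sqrt(p2)))


def _both_normal(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    return (sps.shapiro(x).pvalue >= alpha) and (sps.shapiro(y).pvalue >= alpha)


def auto_compare(x, y, variable: str = "", kind: str = "continuous",
                 alpha_norm: float = 0.05) -> ComparisonResult:
    """Compare two groups, gating the test on Shapiro-Wilk normality.

    ``kind='categorical'`` expects ``x``/``y`` as per-group category count
    vectors (same category order) and runs Pearson's chi-square without
    continuity correction; the effect size is |Cohen's h| on the first
    category's proportion.
    """
    if kind == "categorical":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        table = np.vstack([x, y])
        if table.min() < 0 or (table.sum(axis=0) == 0).any() or table.sum() == 0:
            raise InputError("degenerate contingency table")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        p1 = x[0] / x.sum()
        p2 = y[0] / y.sum()
        return ComparisonResult(variable, "chi-square", float(chi2), float(p),
                                "cohens_h", abs(cohens_h(p1, p2)))

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise InputError("need at least 3 observations per group")
    if _both_normal(x, y, alpha_norm):
        res = sps.ttest_ind(x, y, equal_var=False)
        return ComparisonResult(variable, "t", float(res.statistic),
                                float(res.pvalue), "cohens_d",
                                abs(cohens_d(x, y)))
    if np.all(np.concatenate([x, y]) == x[0]):
        # both groups constant and identical: no evidence of a difference
        return ComparisonResult(variable, "mann-whitney",
                                float(x.size * y.size / 2), 1.0,
                                "cliffs_delta", 0.0)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return ComparisonResult(variable, "mann-whitney", float(res.statistic),
                            float(res.pvalue), "cliffs_delta",
                            abs(cliffs_delta(x, y)))


def ci_mean(mean: float, sd: float, n: int, level: float = 0.95
            ) -> tuple[float, float]:
    """Two-sided t confidence interval for a mean from summary statistics."""
    if n < 2:
        raise InputError("ci_mean needs n >= 2")
    if sd < 0:
        raise InputError("sd must be non-negative")
    tcrit = sps.t.ppf(0.5 + level / 2, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return (mean - half, mean + half)


def _t_power(n: int, d: float, alpha: float, two_tailed: bool) -> float:
    """Exact power of a two-sample t-test (equal n) via the noncentral t."""
    df = 2 * n - 2
    nc = d * math.sqrt(n / 2)
    if two_tailed:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        return float(1 - sps.nct.cdf(tcrit, df, nc)
                     + sps.nct.cdf(-tcrit, df, nc))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(1 - sps.nct.cdf(tcrit, df, nc))


def required_n(d: float, alpha: float = 0.05, power: float = 0.80,
               two_tailed: bool = True, n_max: int = 100000) -> int:
    """Smallest per-group n whose exact noncentral-t power meets the target."""
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ConfigurationError("require d > 0, alpha and power in (0, 1)")
    for n in range(2, n_max + 1):
        if _t_power(n, d, alpha, two_tailed) >= power:
            return n
    raise ConfigurationError("required sample size exceeds n_max")


def gated_correlation(x, y, alpha_norm: float = 0.05) -> CorrelationResult:
    """Pearson when both margins pass Shapiro-Wilk, Spearman otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise InputError("need >= 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult("none", float("nan"), float("nan"))
    if _both_normal(x, y, alpha_norm):
        r, p = sps.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p))
    r, p = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(r), float(p))


def round_half_up(value: float, decimals: int = 3) -> float:
    """Display rounding with ties away from zero, as clinical reports use."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
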