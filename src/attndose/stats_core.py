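"""Shared statistical primitives.

Conventions fixed for reproducibility: the 2x2 chi-square carries no
continuity correction, Kruskal-Wallis p-values use the chi-square
approximation, and eta-squared is SS_between / SS_total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    effect_size: Optional[float] = None  # eta-squared where applicable
    flagged: bool = False
    note: str = ""


@dataclass
class ProportionComparison:
    statistic: float
    df: float
    p: float
    p_a: float
    p_b: float
    se_a: float
    se_b: float
    flagged: bool = False


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group must have n >= 2")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=0.0, df=len(groups) - 1, p=1.0,
                          flagged=True, note="all observations identical")
    h, p = stats.kruskal(*arrays)
    return TestResult(statistic=float(h), df=len(groups) - 1, p=float(p))


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA with eta^2 = SS_between / SS_total."""
    if len(groups) < 2:
        raise ValueError("one_way_anova needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group must have n >= 2")
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_total = float(np.sum((pooled - grand) ** 2))
    df_between = len(arrays) - 1
    df_within = pooled.size - len(arrays)
    if ss_total <= 1e-300:
        return TestResult(statistic=0.0, df=df_between, p=1.0, effect_size=0.0,
                          flagged=True, note="zero total variance")
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    ss_within = ss_total - ss_between
    eta_sq = ss_between / ss_total
    if ss_within <= 1e-300:
        # distinct means, no within-group variance: F diverges
        return TestResult(statistic=np.inf, df=df_between, p=0.0,
                          effect_size=eta_sq, flagged=True,
                          note="zero within-group variance")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return TestResult(statistic=float(f), df=df_between, p=p, effect_size=eta_sq)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> List[bool]:
    """Strict Bonferroni flags: significant iff p < alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return []
    return list(p < alpha / m)


def bonferroni_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Adjusted p-values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def chi_square_proportions(
    hits_a: int, n_a: int, hits_b: int, n_b: int
) -> ProportionComparison:
    """Pearson chi-square (df=1, no continuity correction) on a 2x2 table."""
    if n_a < 1 or n_b < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= hits_a <= n_a and 0 <= hits_b <= n_b):
        raise ValueError("hit counts must lie in [0, n]")
    p_a, p_b = hits_a / n_a, hits_b / n_b
    se_a = float(np.sqrt(p_a * (1 - p_a) / n_a))
    se_b = float(np.sqrt(p_b * (1 - p_b) / n_b))
    table = np.array([[hits_a, n_a - hits_a], [hits_b, n_b - hits_b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return ProportionComparison(0.0, 1, 1.0, p_a, p_b, se_a, se_b, flagged=True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ProportionComparison(float(chi2), 1, float(p), p_a, p_b, se_a, se_b)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on n < 3 or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
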