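"""Behavioral scoring and group-level statistics.

Covers the full statistical surface of the analysis: signal-detection
d' with extreme-rate correction, the 1.5-SD outlier rule, nonparametric
group comparisons (Mann-Whitney U, Kruskal-Wallis), the Shapiro-Wilk
normality gate, Pearson brain-behavior correlations, Cohen's d effect
sizes, and two-sided p-values from t statistics.  All distributional
work is delegated to scipy.stats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .synth import BehavioralSession, SignalDetectionCounts

__all__ = [
    "TestResult",
    "dprime",
    "remove_outliers",
    "mann_whitney",
    "kruskal_wallis",
    "shapiro_wilk_gate",
    "pearson_brain_behavior",
    "cohens_d",
    "t_to_p",
    "rank_residualize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    statistic: float
    p_value: float
    effect_size: float | None = None
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Signal detection
# ---------------------------------------------------------------------------

def dprime(
    session: BehavioralSession | SignalDetectionCounts,
    condition: str | None = None,
) -> float:
    """Sensitivity d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).

    Extreme rates 0 and 1 are replaced by ``1/(2N)`` and ``1 - 1/(2N)``
    (N = trials in that class) so the quantile stays finite.  Negative
    values arise when the false-alarm rate exceeds the hit rate.
    """
    if isinstance(session, BehavioralSession):
        if condition is None:
            if len(session.conditions) != 1:
                raise ValueError(
                    "session has multiple conditions; pass `condition`"
                )
            condition = next(iter(session.conditions))
        counts = session[condition]
    else:
        counts = session
    if counts.n_signal_trials == 0 or counts.n_noise_trials == 0:
        raise ValueError("both trial classes must contain trials")

    def _corrected(k: int, n: int) -> float:
        rate = k / n
        if rate <= 0:
            return 1 / (2 * n)
        if rate >= 1:
            return 1 - 1 / (2 * n)
        return rate

    h = _corrected(counts.hits, counts.n_signal_trials)
    fa = _corrected(counts.false_alarms, counts.n_noise_trials)
    return float(sps.norm.ppf(h) - sps.norm.ppf(fa))


# ---------------------------------------------------------------------------
# Outlier rule
# ---------------------------------------------------------------------------

def remove_outliers(
    values: np.ndarray, k: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass k-SD outlier removal.

    Subjects whose value deviates from the full-group mean by at least
    ``k`` group standard deviations are flagged.  The rule is applied
    once (mean and SD from the complete group, not re-estimated), so a
    second application to the kept set may remove more — by design this
    is the non-iterated variant.

    Returns ``(kept_indices, removed_indices)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 subjects for the outlier rule")
    mu = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; no outliers removed")
        return np.arange(values.size), np.array([], dtype=int)
    mask = np.abs(values - mu) >= k * sd
    return np.flatnonzero(~mask), np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def mann_whitney(
    group_a: np.ndarray, group_b: np.ndarray, exact_max_n: int = 12
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` observations (and no ties); larger samples use the
    tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    small = a.size <= exact_max_n and b.size <= exact_max_n
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=(a.size, b.size),
    )


def kruskal_wallis(*groups: np.ndarray) -> TestResult:
    """Kruskal-Wallis rank ANOVA with tie correction (chi-square p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=0.0, p_value=1.0,
            n_per_group=tuple(g.size for g in arrays),
        )
    res = sps.kruskal(*arrays)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=tuple(g.size for g in arrays),
    )


def shapiro_wilk_gate(values: np.ndarray, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality check used to justify nonparametric tests.

    The pipeline always takes the nonparametric path; this gate is
    logged, not branched on.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.all(values == values[0]):
        raise ValueError("constant input has no defined normality statistic")
    res = sps.shapiro(values)
    normal = res.pvalue > alpha
    logger.info(
        "Shapiro-Wilk W=%.3f p=%.4g -> %s; nonparametric tests used regardless",
        res.statistic, res.pvalue, "normal" if normal else "non-normal",
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_per_group=(values.size,),
    )


def pearson_brain_behavior(
    behavior: np.ndarray, neural: np.ndarray
) -> TestResult:
    """Pearson correlation between a behavioral rate and a neural feature."""
    x = np.asarray(behavior, dtype=float)
    y = np.asarray(neural, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    res = sps.pearsonr(x, y)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        n_per_group=(x.size,),
    )


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (A minus B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n >= 2")
    na, nb = a.size, b.size
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def t_to_p(t: float, df: int) -> float:
    """Two-sided p-value of a t statistic: ``2 * (1 - F_t(|t|; df))``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2 * sps.t.sf(abs(t), df))


def rank_residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residualize ranked values on a ranked covariate.

    Optional age-adjustment for the nonparametric group tests: both the
    feature and the covariate are rank-transformed and the least-squares
    projection of the feature ranks onto the covariate ranks is removed.
    """
    v = sps.rankdata(np.asarray(values, dtype=float))
    c = sps.rankdata(np.asarray(covariate, dtype=float))
    c_centered = c - c.mean()
    denom = (c_centered**2).sum()
    if denom == 0:
        return v - v.mean()
    beta = ((v - v.mean()) * c_centered).sum() / denom
    return v - v.mean() - beta * c_centered
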