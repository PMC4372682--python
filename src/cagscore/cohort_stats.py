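"""Two-group comparisons and power-based sample-size estimation.

The statistical toolkit used throughout the cohort analysis: unpaired
pooled-variance t tests for normally distributed traits, the unpaired
Mann-Whitney U test otherwise (the automatic choice screens each group
with Shapiro-Wilk at alpha = 0.05 and records the decision), per-group
mean +/- sample-SD summaries, and the classic two-sample normal-
approximation sample-size formula

    n = ceil( 2 (z_{1-alpha/2} + z_{power})^2 s^2 / (mu_a - mu_b)^2 )

with s the pooled SD sqrt((sd_a^2 + sd_b^2)/2).  A noncentral-t
refinement (which can return one or two more animals per group) is
available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.power import tt_ind_solve_power

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PowerSpec:
    """Design targets for sample-size estimation (two-sided alpha)."""

    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    normality_p: tuple[Optional[float], Optional[float]] = (None, None)


def group_summary(values: Sequence[float]) -> tuple[float, Optional[float], int]:
    """Arithmetic mean, sample SD (n-1; None when n < 2) and n."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("group_summary requires at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return mean, sd, int(arr.size)


def _normal_p(values: np.ndarray) -> Optional[float]:
    # Shapiro-Wilk is undefined for constant samples; treat those as
    # non-normal so the comparison falls back to the rank test.
    if np.ptp(values) == 0:
        return 0.0
    return float(stats.shapiro(values).pvalue)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "auto",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided unpaired comparison of two groups of trait values.

    ``method="auto"`` runs a Shapiro-Wilk screen on each group at
    alpha = 0.05 and uses the pooled-variance t test when both pass,
    otherwise the Mann-Whitney U test.  Forcing ``method="t"`` on data
    that fails the screen is allowed but logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if method not in ("auto", "t", "mann_whitney"):
        raise ValueError(f"unknown method {method!r}")

    p_norm_a, p_norm_b = _normal_p(a), _normal_p(b)
    both_normal = p_norm_a >= NORMALITY_ALPHA and p_norm_b >= NORMALITY_ALPHA
    if method == "auto":
        test = "t" if both_normal else "mann_whitney"
    else:
        test = method
        if test == "t" and not both_normal:
            logger.warning(
                "t test forced on groups failing the normality screen "
                "(Shapiro p = %.3g, %.3g)", p_norm_a, p_norm_b,
            )

    if test == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        group_labels=labels,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(p_norm_a, p_norm_b),
    )


def sample_size_two_groups(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    spec: PowerSpec = PowerSpec(),
    method: str = "normal",
) -> int:
    """Animals per group to detect the difference of two means.

    ``method="normal"`` uses the closed-form normal approximation (the
    conventional quick estimate); ``method="noncentral_t"`` solves the exact
    noncentral-t power equation and is typically one animal larger.  Either
    way at least two per group are required for a variance estimate.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("group SDs must be positive")
    diff = mean_a - mean_b
    if diff == 0:
        raise ValueError("zero mean difference: required n is unbounded")
    pooled_var = (sd_a**2 + sd_b**2) / 2.0
    if method == "normal":
        z_a = stats.norm.ppf(1 - spec.alpha / 2)
        z_b = stats.norm.ppf(spec.power)
        n = 2 * (z_a + z_b) ** 2 * pooled_var / diff**2
        n_int = math.ceil(n)
    elif method == "noncentral_t":
        effect = abs(diff) / math.sqrt(pooled_var)
        n = tt_ind_solve_power(
            effect_size=effect, alpha=spec.alpha, power=spec.power,
            ratio=1.0, alternative="two-sided",
        )
        n_int = math.ceil(n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return max(2, n_int)


def empirical_power(
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    n: int,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the two-sided pooled t test at n per group.

    Draws ``reps`` pairs of normal samples with the given group means and
    SDs and returns the fraction of replicates rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(mean_a, sd_a, size=(reps, n))
    b = rng.normal(mean_b, sd_b, size=(reps, n))
    p = stats.ttest_ind(a, b, axis=1, equal_var=True).pvalue
    return float(np.mean(p < alpha))


def type_i_error_rate(
    n: int = 10, alpha: float = 0.05, reps: int = 10_000, seed: int = 0
) -> float:
    """Monte-Carlo null rejection rate of the pooled t test.

    Both groups are drawn from the same standard normal; the returned rate
    should sit at ``alpha`` up to binomial sampling error.
    """
    return empirical_power(0.0, 1.0, 0.0, 1.0, n, alpha, reps, seed)


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p values (helper; no correction is applied by default)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
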