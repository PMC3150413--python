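"""Two-sample tests at atom and subnetwork level.

The theoretical model is a two-group comparison with known noise variance:
per atom j, group 1 observes mu_j + eps and group 2 observes
mu_j + Delta_j + eps with eps ~ N(0, sigma^2) i.i.d.  The atom-wise test is
a z-test on the group mean difference D_j; the subset-wise test is a z-test
on the mean of the D_j over the atoms of a subset (variance shrinks by the
subset size m_i).  For real data the package also offers the Student t,
the Wilcoxon–Mann–Whitney rank test, and a Hotelling-type statistic for
p-variate summaries with an F reference distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestSpec",
    "z_test_diff",
    "subset_mean_test",
    "t_test",
    "wilcoxon_rank_test",
    "hotelling_f_test",
]

ALTERNATIVES = ("greater", "two-sided")


@dataclass(frozen=True)
class TestSpec:
    """Which two-sample test to run and against which alternative.

    ``alternative='greater'`` tests for a positive shift in group 2
    (the one-sided model of the power theory); ``'two-sided'`` is the
    application default.  ``sigma`` is the known noise SD (z tests only).
    """

    test: str = "t"
    alternative: str = "two-sided"
    sigma: float | None = None
    level: float = 0.05

    def __post_init__(self) -> None:
        if self.test not in ("z_known_sigma", "t", "wilcoxon", "hotelling_f"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.test == "z_known_sigma" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("z test requires a known sigma > 0")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")


def _normal_p(z: float | np.ndarray, alternative: str):
    if alternative == "greater":
        return stats.norm.sf(z)
    return 2 * stats.norm.sf(np.abs(z))


def z_test_diff(
    x1: np.ndarray,
    x2: np.ndarray,
    sigma: float,
    alternative: str = "greater",
) -> tuple[float, float]:
    """z-test on D = mean(x2) - mean(x1) with known per-observation SD.

    Under the null, D ~ N(0, sigma^2 (1/n1 + 1/n2)); with equal group
    sizes n this is the familiar 2 sigma^2 / n.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("empty sample")
    d = x2.mean() - x1.mean()
    sd = sigma * np.sqrt(1.0 / x1.size + 1.0 / x2.size)
    return float(d), float(_normal_p(d / sd, alternative))


def subset_mean_test(
    diffs: np.ndarray,
    sigma: float,
    n: int,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Test the mean of per-atom group differences over one subset.

    ``diffs`` holds D_j = mean2_j - mean1_j for the m_i atoms of the
    subset, each with null variance 2 sigma^2 / n (equal group sizes n).
    The summary T_i = mean(D_j) has null distribution
    N(0, 2 sigma^2 / (n m_i)) — the variance shrinks with the subset size.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    diffs = np.asarray(diffs, float)
    if diffs.size == 0:
        raise ValueError("empty subset")
    t_i = diffs.mean()
    sd = sigma * np.sqrt(2.0 / (n * diffs.size))
    return float(t_i), float(_normal_p(t_i / sd, alternative))


def t_test(
    x1: np.ndarray, x2: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Pooled-variance two-sample Student t-test (statistic for group2 - group1)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if np.ptp(x1) == 0 and np.ptp(x2) == 0 and x1.mean() == x2.mean():
        warnings.warn("all values identical in both groups; p set to 1")
        return 0.0, 1.0
    res = stats.ttest_ind(
        x2, x1, alternative=("greater" if alternative == "greater" else "two-sided")
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_test(
    g1: np.ndarray, g2: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon–Mann–Whitney rank test for a location shift of group 2.

    Uses the exact null distribution when n1 + n2 <= 12 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction.  Returns the Mann–Whitney U of group 2 over
    group 1.  ``alternative='greater'`` means group 2 stochastically larger.
    """
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical in both groups; p set to 1")
        return float(g1.size * g2.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (g1.size + g2.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(g2, g1, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def hotelling_f_test(
    s1: np.ndarray, s2: np.ndarray, cond_bound: float = 1e12
) -> tuple[float, float]:
    """Two-sample Hotelling-type test on p-variate summary statistics.

    ``s1`` (n1 x p) and ``s2`` (n2 x p) are the per-subject summary vectors
    of the two cohorts.  With t = colmean(s2) - colmean(s1) and C the pooled
    covariance scaled by (1/n1 + 1/n2),

        f = (n1 + n2 - p - 1) / ((n1 + n2 - 2) p) * t' C^{-1} t

    follows an F(p, n1 + n2 - p - 1) distribution under the null.  At p = 1
    this is exactly the squared pooled two-sample t statistic.
    """
    s1 = np.atleast_2d(np.asarray(s1, float))
    s2 = np.atleast_2d(np.asarray(s2, float))
    n1, p = s1.shape
    n2, p2 = s2.shape
    if p != p2:
        raise ValueError("groups have different summary dimensions")
    if n1 + n2 - 2 <= p:
        raise ValueError(
            f"need n1 + n2 - 2 > p for an invertible covariance (got p={p}, "
            f"n1+n2-2={n1 + n2 - 2})"
        )
    t = s2.mean(axis=0) - s1.mean(axis=0)
    c1 = np.cov(s1, rowvar=False).reshape(p, p)
    c2 = np.cov(s2, rowvar=False).reshape(p, p)
    pooled = ((n1 - 1) * c1 + (n2 - 1) * c2) / (n1 + n2 - 2)
    c = pooled * (1.0 / n1 + 1.0 / n2)
    if np.linalg.cond(c) > cond_bound:
        raise np.linalg.LinAlgError(
            "singular pooled covariance; use fewer summary components or more subjects"
        )
    t2 = float(t @ np.linalg.solve(c, t))
    f = (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p) * t2
    pval = float(stats.f.sf(f, p, n1 + n2 - p - 1))
    return float(f), pval
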