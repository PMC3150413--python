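"""Closed-form power theory: atom-wise vs subset-wise analysis.

Model: m atoms, two groups of n subjects each, known noise SD sigma.
Affected atoms carry a positive mean shift Delta; tests are one-sided
with Bonferroni control at global level alpha — over the m atoms for the
atom-wise analysis (AWA) and over the s subset means for the subset-wise
analysis (SWA).  A subset of size m_i with a proportion pi of affected
atoms has its effect diluted to pi * Delta but its noise SD shrunk by
1/sqrt(m_i), giving:

    c_AWA  = sigma sqrt(2/n) PhiInv(1 - alpha/m)
    c_SWA  = sigma sqrt(2/(n m_i)) PhiInv(1 - alpha/s)
    Pow_AWA = 1 - Phi(PhiInv(1 - alpha/m) - Delta sqrt(n/2) / sigma)
    Pow_SWA = 1 - Phi(PhiInv(1 - alpha/s) - pi Delta sqrt(n m_i / 2) / sigma)

The two power curves cross at the proportion pi*; the SWA wins whenever
pi > pi*, and pi* < 1/sqrt(m_i) always (strictly when s < m), so a subset
containing more than sqrt(m_i) affected atoms is always detected with
higher power than its individual atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "PiStar",
    "critical_value_awa",
    "critical_value_swa",
    "power_awa",
    "power_swa",
    "pi_star",
]


@dataclass(frozen=True)
class PowerSpec:
    """Parameter bundle for the analytic power comparison.

    m: total atoms; s: subsets; m_i: size of the subset under study;
    delta: raw per-atom effect (weight units); sigma: known noise SD;
    n: per-group sample size (equal-n model); alpha: global level;
    pi: proportion of affected atoms in the subset.
    """

    m: int
    s: int
    m_i: int
    delta: float
    sigma: float = 1.0
    n: int = 20
    alpha: float = 0.05
    pi: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must be in [0, 1]")
        if not self.m >= self.s >= 1:
            raise ValueError("need m >= s >= 1")
        if self.m_i < 1:
            raise ValueError("m_i must be >= 1")
        if self.sigma <= 0 or self.n <= 0:
            raise ValueError("sigma and n must be > 0")

    def with_(self, **kw) -> "PowerSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class PiStar:
    """Crossover proportion, with a flag for values outside [0, 1].

    ``value`` is the raw solution of Pow_SWA(pi) = Pow_AWA (not clipped);
    ``in_range`` is False when it falls outside [0, 1], which can happen
    at extreme effect sizes.
    """

    value: float
    in_range: bool

    def __float__(self) -> float:
        return self.value


def _quantile(tail: float) -> float:
    if tail >= 1:
        raise ValueError("per-test level alpha/k must be < 1")
    return float(stats.norm.ppf(1.0 - tail))


def critical_value_awa(spec: PowerSpec) -> float:
    """One-sided Bonferroni critical value on the atom mean difference."""
    return spec.sigma * np.sqrt(2.0 / spec.n) * _quantile(spec.alpha / spec.m)


def critical_value_swa(spec: PowerSpec) -> float:
    """One-sided Bonferroni critical value on the subset mean difference.

    Depends on the reduction in the number of tests (s vs m) *and* on the
    1/sqrt(m_i) reduction of the noise SD from averaging within the subset.
    """
    return (
        spec.sigma
        * np.sqrt(2.0 / (spec.n * spec.m_i))
        * _quantile(spec.alpha / spec.s)
    )


def power_awa(spec: PowerSpec) -> float:
    """Probability of detecting one affected atom (Bonferroni over m)."""
    snr = spec.delta * np.sqrt(spec.n / 2.0) / spec.sigma
    return float(stats.norm.sf(_quantile(spec.alpha / spec.m) - snr))


def power_swa(spec: PowerSpec) -> float:
    """Probability of detecting a subset with a proportion pi of affected atoms."""
    snr = spec.pi * spec.delta * np.sqrt(spec.n * spec.m_i / 2.0) / spec.sigma
    return float(stats.norm.sf(_quantile(spec.alpha / spec.s) - snr))


def pi_star(spec: PowerSpec) -> PiStar:
    """Proportion of affected atoms at which SWA and AWA power coincide.

    pi* = [PhiInv(1 - alpha/s) - PhiInv(1 - alpha/m) + Delta sqrt(n/2)/sigma]
          / (Delta sqrt(n m_i / 2) / sigma)

    Always <= 1/sqrt(m_i) (strictly when s < m): since alpha/s >= alpha/m,
    the quantile difference in the numerator is non-positive.
    """
    if spec.delta <= 0:
        raise ValueError("pi* requires delta > 0")
    snr = spec.delta * np.sqrt(spec.n / 2.0) / spec.sigma
    num = _quantile(spec.alpha / spec.s) - _quantile(spec.alpha / spec.m) + snr
    value = float(num / (snr * np.sqrt(spec.m_i)))
    return PiStar(value=value, in_range=0.0 <= value <= 1.0)
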