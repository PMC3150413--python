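"""Multiple-testing corrections and error accounting.

When m hypotheses are tested at once, controlling the per-test level alone
lets false positives accumulate (10,000 true-null tests at level 0.05
produce 500 expected false positives).  Two standard remedies:

* Bonferroni — each test at level alpha/m; controls the family-wise error
  rate FWER = P(FP > 0) strongly.
* Benjamini–Hochberg step-up (BH95) — controls the false discovery rate
  FDR = E[FP / R] (0 when R = 0), trading strictness for power.

Both are exposed in adjusted-p form (monotone cumulative-minimum
transform) and in raw threshold form; a vectorized row-wise variant serves
the Monte-Carlo engine.  ``tally`` fills the standard multiple-comparison
outcome table (TP/FP/TN/FN, R) from ground-truth and rejection flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorTally",
    "bonferroni",
    "bh95",
    "bh_reject_rows",
    "tally",
]


@dataclass(frozen=True)
class ErrorTally:
    """Outcome counts of a multiple-comparison experiment.

    Identities: FP + TN = m0, TP + FN = m1, FP + TP = R, m0 + m1 = m.
    """

    m: int
    m0: int
    m1: int
    fp: int
    fn: int
    tp: int
    tn: int

    @property
    def r(self) -> int:
        return self.fp + self.tp

    @property
    def any_false_positive(self) -> bool:
        """FWER indicator for this realization."""
        return self.fp > 0

    @property
    def fdp(self) -> float:
        """False discovery proportion FP / R, defined as 0 when R = 0."""
        return self.fp / self.r if self.r > 0 else 0.0

    @property
    def average_power(self) -> float:
        """TP / m1, defined as 0 when there are no false nulls."""
        return self.tp / self.m1 if self.m1 > 0 else 0.0


def _check_pvals(pvals: np.ndarray) -> np.ndarray:
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: adjusted p = min(1, m p); reject iff p <= alpha/m."""
    p = _check_pvals(pvals)
    m = p.size
    adjusted = np.minimum(1.0, m * p)
    return adjusted, p <= alpha / m


def bh95(pvals: np.ndarray, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure at FDR level q.

    Sort p ascending, find the largest k with p_(k) <= k q / m and reject
    the k smallest (ties rejected together).  Adjusted p-values are the
    monotone cumulative minimum of m p_(j) / j from the largest rank down;
    rejecting ``adjusted <= q`` reproduces the step-up decision.
    """
    p = _check_pvals(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj_sorted = np.minimum.accumulate((m / np.arange(m, 0, -1)) * ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(1.0, adj_sorted)
    passing = np.nonzero(ranked <= (np.arange(1, m + 1) * q / m))[0]
    reject = np.zeros(m, bool)
    if passing.size:
        threshold = ranked[passing[-1]]
        reject = p <= threshold
    return adjusted, reject


def bh_reject_rows(pmat: np.ndarray, q: float) -> np.ndarray:
    """Row-wise BH95 rejection masks for a (replicates x m) p-value matrix."""
    pmat = np.asarray(pmat, float)
    reps, m = pmat.shape
    ranked = np.sort(pmat, axis=1)
    crit = np.arange(1, m + 1) * q / m
    passing = ranked <= crit
    # largest passing rank per row; threshold = p at that rank (or -inf if none)
    k = np.where(passing.any(axis=1), passing.shape[1] - 1 - np.argmax(passing[:, ::-1], axis=1), -1)
    thresh = np.where(k >= 0, ranked[np.arange(reps), np.maximum(k, 0)], -np.inf)
    return pmat <= thresh[:, None]


def tally(true_flags: np.ndarray, rejected_flags: np.ndarray) -> ErrorTally:
    """Fill the outcome table from ground truth and rejections.

    ``true_flags[j]`` is True when hypothesis j is a false null (a real
    effect exists); ``rejected_flags[j]`` when it was declared significant.
    """
    truth = np.asarray(true_flags, bool)
    rej = np.asarray(rejected_flags, bool)
    if truth.shape != rej.shape:
        raise ValueError("true/rejected flag lengths differ")
    tp = int(np.sum(truth & rej))
    fp = int(np.sum(~truth & rej))
    fn = int(np.sum(truth & ~rej))
    tn = int(np.sum(~truth & ~rej))
    return ErrorTally(m=truth.size, m0=fp + tn, m1=tp + fn, fp=fp, fn=fn, tp=tp, tn=tn)
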