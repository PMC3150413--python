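"""Monte-Carlo engine for the power and error-rate study.

Replicates the simulation design of the power theory: m = s * m_i atoms
split into s equal subsets, s1 of them affected, each affected subset
containing k_i = pi * m_i atoms shifted by the raw effect Delta; all atom
noise is independent Gaussian with known sigma and two groups of n
subjects.  Because the atom-wise and subset-wise z statistics depend on
the data only through the per-atom group mean differences
D_j ~ N(shift_j, 2 sigma^2 / n), the engine draws the D_j directly.

All routines are deterministic given a seed; replicates are chunked to
bound memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multiplicity import bh_reject_rows
from .power import PowerSpec, critical_value_swa, power_awa, power_swa

__all__ = [
    "SimConfig",
    "simulate_power_curves",
    "simulate_error_rates",
    "simulate_expected_fp",
    "simulate_prop1",
    "simulate_two_stage",
]

_CHUNK_CELLS = 4_000_000  # max replicates * m drawn at once


@dataclass(frozen=True)
class SimConfig:
    """Grid for the power-curve study (defaults follow the theory setup)."""

    deltas: tuple[float, ...] = (1.0, 2.0)
    subset_sizes: tuple[int, ...] = (4, 8, 16)
    s: int = 32
    s1: int = 8
    n: int = 20
    sigma: float = 1.0
    level: float = 0.05
    correction: str = "bonferroni"
    replicates: int = 10_000
    seed: int = 0
    pi_grid: tuple[float, ...] | None = None  # default: k/m_i for k=0..m_i

    def __post_init__(self) -> None:
        if not 1 <= self.s1 <= self.s:
            raise ValueError("need 1 <= s1 <= s")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.correction not in ("bonferroni", "bh95"):
            raise ValueError("correction must be 'bonferroni' or 'bh95'")


def _shift_vector(s: int, s1: int, m_i: int, k_i: int, delta: float) -> np.ndarray:
    """Per-atom mean shifts: first k_i atoms of the first s1 subsets affected."""
    shifts = np.zeros(s * m_i)
    for b in range(s1):
        shifts[b * m_i: b * m_i + k_i] = delta
    return shifts


def _chunks(replicates: int, m: int):
    step = max(1, _CHUNK_CELLS // max(m, 1))
    done = 0
    while done < replicates:
        take = min(step, replicates - done)
        yield take
        done += take


def _run_cell(
    rng: np.random.Generator,
    s: int,
    s1: int,
    m_i: int,
    k_i: int,
    delta: float,
    n: int,
    sigma: float,
    level: float,
    correction: str,
    replicates: int,
):
    """Per-replicate AWA and SWA outcome arrays for one grid cell.

    Returns (awa_power, swa_power, awa_fp_any, swa_fp_any, awa_fdp, swa_fdp)
    arrays of length ``replicates`` (power entries are NaN when m1 = 0).
    """
    m = s * m_i
    shifts = _shift_vector(s, s1, m_i, k_i, delta)
    atom_truth = shifts > 0
    subset_truth = np.zeros(s, bool)
    subset_truth[:s1] = k_i > 0
    sd_atom = sigma * np.sqrt(2.0 / n)
    sd_subset = sigma * np.sqrt(2.0 / (n * m_i))
    m1 = int(atom_truth.sum())
    s1_eff = int(subset_truth.sum())

    out = {k: [] for k in ("ap", "sp", "afp", "sfp", "afdp", "sfdp")}
    for take in _chunks(replicates, m):
        d = rng.standard_normal((take, m)) * sd_atom + shifts
        t_sub = d.reshape(take, s, m_i).mean(axis=2)
        if correction == "bonferroni":
            rej_a = d > sd_atom * stats.norm.ppf(1 - level / m)
            rej_s = t_sub > sd_subset * stats.norm.ppf(1 - level / s)
        else:
            rej_a = bh_reject_rows(stats.norm.sf(d / sd_atom), level)
            rej_s = bh_reject_rows(stats.norm.sf(t_sub / sd_subset), level)
        tp_a = rej_a[:, atom_truth].sum(axis=1)
        fp_a = rej_a[:, ~atom_truth].sum(axis=1)
        tp_s = rej_s[:, subset_truth].sum(axis=1)
        fp_s = rej_s[:, ~subset_truth].sum(axis=1)
        out["ap"].append(tp_a / m1 if m1 else np.full(take, np.nan))
        out["sp"].append(tp_s / s1_eff if s1_eff else np.full(take, np.nan))
        out["afp"].append(fp_a > 0)
        out["sfp"].append(fp_s > 0)
        out["afdp"].append(fp_a / np.maximum(fp_a + tp_a, 1))
        out["sfdp"].append(fp_s / np.maximum(fp_s + tp_s, 1))
    return {k: np.concatenate(v) for k, v in out.items()}


def simulate_power_curves(config: SimConfig) -> pd.DataFrame:
    """Average power of AWA and SWA across the (delta, m_i, pi) grid.

    One row per grid cell with the Monte-Carlo mean power of detecting
    affected atoms (AWA) and affected subsets (SWA), their standard
    errors, and the analytic closed-form values for comparison.  Only pi
    values with integral k_i = pi * m_i are simulated; average power is
    NaN in cells with no truly affected atoms (pi = 0).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for delta in config.deltas:
        for m_i in config.subset_sizes:
            if config.pi_grid is None:
                k_grid = list(range(m_i + 1))
            else:
                k_grid = sorted({int(round(pi * m_i)) for pi in config.pi_grid
                                 if abs(pi * m_i - round(pi * m_i)) < 1e-9})
            for k_i in k_grid:
                pi = k_i / m_i
                cell = _run_cell(
                    rng, config.s, config.s1, m_i, k_i, delta, config.n,
                    config.sigma, config.level, config.correction,
                    config.replicates,
                )
                spec = PowerSpec(
                    m=config.s * m_i, s=config.s, m_i=m_i, delta=delta,
                    sigma=config.sigma, n=config.n, alpha=config.level, pi=pi,
                )
                ap, sp = cell["ap"], cell["sp"]
                rows.append({
                    "procedure": config.correction,
                    "delta": delta, "m_i": m_i, "pi": pi, "k_i": k_i,
                    "avg_power_awa": np.nanmean(ap) if np.isfinite(ap).any() else np.nan,
                    "avg_power_swa": np.nanmean(sp) if np.isfinite(sp).any() else np.nan,
                    "se_awa": (np.nanstd(ap) / np.sqrt(len(ap))) if np.isfinite(ap).any() else np.nan,
                    "se_swa": (np.nanstd(sp) / np.sqrt(len(sp))) if np.isfinite(sp).any() else np.nan,
                    "analytic_power_awa": power_awa(spec),
                    "analytic_power_swa": power_swa(spec),
                })
    return pd.DataFrame(rows)


def simulate_error_rates(
    s: int,
    m_i: int,
    s1: int = 0,
    k_i: int | None = None,
    delta: float = 0.0,
    n: int = 20,
    sigma: float = 1.0,
    level: float = 0.05,
    correction: str = "bonferroni",
    replicates: int = 2000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Empirical FWER, FDR and average power at atom and subnetwork level.

    FWER is the fraction of replicates with at least one false positive;
    FDR is the mean false-discovery proportion FP / max(R, 1); both come
    with binomial/empirical standard errors.  ``s1 = 0`` (or delta = 0)
    gives the global-null configuration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k_i is None:
        k_i = m_i if (s1 > 0 and delta > 0) else 0
    cell = _run_cell(
        rng, s, max(s1, 1) if s1 else 1, m_i, k_i if s1 else 0, delta, n,
        sigma, level, correction, replicates,
    )
    # s1=0 is encoded as k_i=0 in the first subset: no atom/subset is truly affected

    def _rate(x):
        x = np.asarray(x, float)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size))

    fwer_a, se_fwer_a = _rate(cell["afp"])
    fwer_s, se_fwer_s = _rate(cell["sfp"])
    fdr_a, se_fdr_a = _rate(cell["afdp"])
    fdr_s, se_fdr_s = _rate(cell["sfdp"])
    res = {
        "replicates": replicates,
        "atom": {"fwer": fwer_a, "fwer_se": se_fwer_a, "fdr": fdr_a, "fdr_se": se_fdr_a},
        "subnetwork": {"fwer": fwer_s, "fwer_se": se_fwer_s, "fdr": fdr_s, "fdr_se": se_fdr_s},
    }
    if np.isfinite(cell["ap"]).any():
        res["atom"]["avg_power"] = float(np.nanmean(cell["ap"]))
    if np.isfinite(cell["sp"]).any():
        res["subnetwork"]["avg_power"] = float(np.nanmean(cell["sp"]))
    return res


def simulate_expected_fp(
    m: int,
    alpha: float = 0.05,
    n: int = 20,
    sigma: float = 1.0,
    replicates: int = 200,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Mean false-positive count of m true-null tests at *uncorrected* level alpha.

    Illustrates the multiplicity problem: the expectation is m * alpha.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = sigma * np.sqrt(2.0 / n)
    crit = sd * stats.norm.ppf(1 - alpha)
    counts = []
    for take in _chunks(replicates, m):
        d = rng.standard_normal((take, m)) * sd
        counts.append((d > crit).sum(axis=1))
    counts = np.concatenate(counts)
    return {
        "mean_fp": float(counts.mean()),
        "se": float(counts.std(ddof=1) / np.sqrt(counts.size)),
        "expected": m * alpha,
        "replicates": replicates,
    }


def simulate_prop1(
    alpha: float,
    s: int,
    m_i: int,
    delta: float,
    n: int = 20,
    sigma: float = 1.0,
    target_significant: int = 100_000,
    seed: int | np.random.Generator = 0,
    max_draws: int = 100_000_000,
) -> dict:
    """Count stage-2 failures among stage-1 Bonferroni-significant subsets.

    Draws subsets of m_i atom differences with every atom shifted by
    ``delta``, keeps those whose mean exceeds the stage-1 subset critical
    value (Bonferroni over s at level alpha), and counts how many contain
    no atom exceeding the within-subset Bonferroni critical value (over
    m_i at level alpha).  When ``prop1_condition(alpha, s, m_i)`` holds,
    the count must be zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = PowerSpec(m=max(s * m_i, s), s=s, m_i=m_i, delta=delta, sigma=sigma,
                     n=n, alpha=alpha)
    c_stage1 = critical_value_swa(spec)
    c_stage2 = sigma * np.sqrt(2.0 / n) * stats.norm.ppf(1 - alpha / m_i)
    sd_atom = sigma * np.sqrt(2.0 / n)

    n_sig = 0
    n_viol = 0
    drawn = 0
    batch = max(1, _CHUNK_CELLS // m_i)
    while n_sig < target_significant and drawn < max_draws:
        d = rng.standard_normal((batch, m_i)) * sd_atom + delta
        drawn += batch
        sig = d.mean(axis=1) > c_stage1
        if sig.any():
            sel = d[sig]
            need = target_significant - n_sig
            sel = sel[:need]
            n_sig += sel.shape[0]
            n_viol += int((sel.max(axis=1) <= c_stage2).sum())
    return {"n_significant": n_sig, "n_violations": n_viol, "n_drawn": drawn}


def simulate_two_stage(
    s: int,
    m_i: int,
    s1: int = 0,
    k_i: int = 0,
    delta: float = 0.0,
    n: int = 20,
    sigma: float = 1.0,
    alpha: float = 0.05,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Two-stage Bonferroni procedure vs the global atom-wise analysis.

    Stage 1: subset-mean z tests, Bonferroni over s at level alpha.
    Stage 2: atom z tests inside each selected subset, Bonferroni over m_i
    at level alpha.  Reports, per replicate and averaged: whether any
    stage-2 (false) rejection occurred, and — paired on the same draws —
    the fraction of affected atoms inside stage-1-significant subsets
    detected by stage 2 vs by the global AWA Bonferroni over all m atoms.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = s * m_i
    shifts = _shift_vector(s, s1, m_i, k_i, delta)
    atom_truth = (shifts > 0).reshape(s, m_i)
    sd_atom = sigma * np.sqrt(2.0 / n)
    c1 = sigma * np.sqrt(2.0 / (n * m_i)) * stats.norm.ppf(1 - alpha / s)
    c2 = sd_atom * stats.norm.ppf(1 - alpha / m_i)
    c_awa = sd_atom * stats.norm.ppf(1 - alpha / m)

    any_stage2 = np.zeros(replicates, bool)
    any_stage2_fp = np.zeros(replicates, bool)
    det_two_stage = []
    det_global = []
    done = 0
    for take in _chunks(replicates, m):
        d = rng.standard_normal((take, m)) * sd_atom + shifts
        d3 = d.reshape(take, s, m_i)
        sel = d3.mean(axis=2) > c1  # (take, s)
        rej2 = (d3 > c2) & sel[:, :, None]
        rej_awa = d3 > c_awa
        any_stage2[done:done + take] = rej2.any(axis=(1, 2))
        any_stage2_fp[done:done + take] = (rej2 & ~atom_truth).any(axis=(1, 2))
        # affected atoms inside selected subsets, paired comparison
        in_scope = sel[:, :, None] & atom_truth
        n_scope = in_scope.sum(axis=(1, 2)).astype(float)
        with np.errstate(invalid="ignore"):
            det_two_stage.append((rej2 & atom_truth).sum(axis=(1, 2)) / n_scope)
            det_global.append((rej_awa & in_scope).sum(axis=(1, 2)) / n_scope)
        done += take
    det_two_stage = np.concatenate(det_two_stage)
    det_global = np.concatenate(det_global)
    valid = np.isfinite(det_two_stage)
    res = {
        "replicates": replicates,
        "frac_any_stage2_rejection": float(any_stage2.mean()),
        "frac_any_stage2_false_positive": float(any_stage2_fp.mean()),
    }
    if valid.any():
        a = det_two_stage[valid]
        b = det_global[valid]
        res["conditional_power_two_stage"] = float(a.mean())
        res["conditional_power_global_awa"] = float(b.mean())
        res["paired_diff_se"] = float((a - b).std(ddof=1) / np.sqrt(valid.sum()))
    return res
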