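"""Analysis pipelines: subnetwork-wise, atom-wise, and the two-stage procedure.

The two-stage procedure first runs the subnetwork-wise analysis (SNBA) to
select significant blocks, then performs a local atom-wise investigation
restricted to each selected block, with its own multiplicity correction
over the block's m_i atoms.  Under the known-sigma mean-summary model,
Proposition-1-type conditions guarantee that a Bonferroni-significant
subset mean forces at least one atom through the local Bonferroni test;
the procedure controls false positives weakly (under the global null) but
not strongly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .core import GroupStudy, SubnetworkIndex, TestResult
from .inference import TestSpec, hotelling_f_test
from .multiplicity import bh95, bonferroni
from .summary import SummarySpec, block_summaries

__all__ = [
    "subnetwork_analysis",
    "atomwise_analysis",
    "two_stage_analysis",
    "prop1_condition",
]


def _correct(pvals: np.ndarray, procedure: str, level: float):
    if procedure == "bonferroni":
        return bonferroni(pvals, level)
    if procedure == "bh95":
        return bh95(pvals, level)
    raise ValueError(f"unknown correction {procedure!r}")


def _columnwise_tests(
    x1: np.ndarray, x2: np.ndarray, spec: TestSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column two-sample tests on (n1, k) vs (n2, k) data matrices.

    Zero-variance columns (identical values in both groups) get p = 1 and
    statistic 0, with a warning.
    """
    n1, _ = x1.shape
    n2, _ = x2.shape
    degenerate = (np.ptp(x1, axis=0) == 0) & (np.ptp(x2, axis=0) == 0) & (
        x1[0] == x2[0]
    )
    if spec.test == "z_known_sigma":
        d = x2.mean(axis=0) - x1.mean(axis=0)
        sd = spec.sigma * np.sqrt(1.0 / n1 + 1.0 / n2)
        stat = d
        z = d / sd
        p = stats.norm.sf(z) if spec.alternative == "greater" else 2 * stats.norm.sf(np.abs(z))
    elif spec.test == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(x2, x1, axis=0, alternative=spec.alternative)
        stat, p = res.statistic, res.pvalue
    elif spec.test == "wilcoxon":
        ties = np.array([
            np.unique(np.concatenate([x1[:, j], x2[:, j]])).size < n1 + n2
            for j in range(x1.shape[1])
        ])
        method = "exact" if (n1 + n2 <= 12 and not ties.any()) else "asymptotic"
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(x2, x1, axis=0, alternative=spec.alternative, method=method)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"{spec.test!r} is not a columnwise test")
    stat = np.atleast_1d(np.asarray(stat, float)).copy()
    p = np.atleast_1d(np.asarray(p, float)).copy()
    bad = degenerate | ~np.isfinite(p)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance units; their p set to 1")
        stat[bad] = 0.0
        p[bad] = 1.0
    return stat, p


def subnetwork_analysis(
    study: GroupStudy,
    index: SubnetworkIndex,
    summary: SummarySpec | None = None,
    test: TestSpec | None = None,
    correction: str = "bh95",
    level: float = 0.1,
) -> list[TestResult]:
    """One test per block on per-subject summary statistics (SNBA / SWA)."""
    summary = summary or SummarySpec()
    test = test or TestSpec("wilcoxon")
    s1, s2 = block_summaries(study, index, summary)
    if test.test == "hotelling_f":
        stat = np.empty(index.n_blocks)
        p = np.empty(index.n_blocks)
        for bi in range(index.n_blocks):
            stat[bi], p[bi] = hotelling_f_test(s1[:, bi, :], s2[:, bi, :])
    else:
        if summary.p != 1:
            raise ValueError("multivariate summaries require the hotelling_f test")
        stat, p = _columnwise_tests(s1[:, :, 0], s2[:, :, 0], test)
    adj, rej = _correct(p, correction, level)
    return [
        TestResult(
            unit=b.name, statistic=float(stat[i]), p=float(p[i]),
            p_adj=float(adj[i]), rejected=bool(rej[i]),
            procedure=correction, level=level,
        )
        for i, b in enumerate(index.blocks)
    ]


def atomwise_analysis(
    study: GroupStudy,
    index: SubnetworkIndex,
    channel: str = "density",
    test: TestSpec | None = None,
    correction: str = "bonferroni",
    level: float = 0.05,
) -> list[TestResult]:
    """One test per atom (edge) over the whole matrix (ANBA / AWA)."""
    test = test or TestSpec("wilcoxon")
    x1 = index.atom_matrix(study.group1, channel)
    x2 = index.atom_matrix(study.group2, channel)
    stat, p = _columnwise_tests(x1, x2, test)
    adj, rej = _correct(p, correction, level)
    pairs = index.atom_labels()
    return [
        TestResult(
            unit=f"{a}--{b}", statistic=float(stat[j]), p=float(p[j]),
            p_adj=float(adj[j]), rejected=bool(rej[j]),
            procedure=correction, level=level,
        )
        for j, (a, b) in enumerate(pairs)
    ]


def two_stage_analysis(
    study: GroupStudy,
    index: SubnetworkIndex,
    summary: SummarySpec | None = None,
    stage1_test: TestSpec | None = None,
    stage1_correction: str = "bh95",
    stage1_level: float = 0.1,
    stage2_test: TestSpec | None = None,
    stage2_correction: str = "bonferroni",
    stage2_level: float = 0.05,
    stage2_channel: str | None = None,
    stage2_family: str = "per_block",
) -> tuple[list[TestResult], dict[str, list[TestResult]]]:
    """SNBA selection followed by a local atom-wise investigation.

    Stage 2 tests the atoms of each stage-1-significant block, corrected
    over that block's m_i atoms (``stage2_family='per_block'``, matching
    the two-stage theory) or over the union of all selected blocks'
    atoms (``'union'``, more conservative).  Blocks not significant at
    stage 1 yield no stage-2 tests; no significant block at all yields an
    empty stage-2 result.
    """
    summary = summary or SummarySpec()
    stage2_test = stage2_test or TestSpec("wilcoxon")
    stage2_channel = stage2_channel or summary.channel
    if stage2_family not in ("per_block", "union"):
        raise ValueError("stage2_family must be 'per_block' or 'union'")
    stage1 = subnetwork_analysis(
        study, index, summary, stage1_test, stage1_correction, stage1_level
    )
    selected = [i for i, r in enumerate(stage1) if r.rejected]
    if not selected:
        return stage1, {}

    x1 = index.atom_matrix(study.group1, stage2_channel)
    x2 = index.atom_matrix(study.group2, stage2_channel)
    pairs = index.atom_labels()

    per_block_stats = {}
    for bi in selected:
        sl = index.block_slices[bi]
        stat, p = _columnwise_tests(x1[:, sl], x2[:, sl], stage2_test)
        per_block_stats[bi] = (sl, stat, p)

    stage2: dict[str, list[TestResult]] = {}
    if stage2_family == "union":
        all_p = np.concatenate([p for _, _, p in per_block_stats.values()])
        adj_all, rej_all = _correct(all_p, stage2_correction, stage2_level)
        offset = 0
        split = {}
        for bi, (sl, stat, p) in per_block_stats.items():
            k = p.size
            split[bi] = (sl, stat, p, adj_all[offset:offset + k], rej_all[offset:offset + k])
            offset += k
    else:
        split = {}
        for bi, (sl, stat, p) in per_block_stats.items():
            adj, rej = _correct(p, stage2_correction, stage2_level)
            split[bi] = (sl, stat, p, adj, rej)

    for bi, (sl, stat, p, adj, rej) in split.items():
        block = index.blocks[bi]
        rows = []
        for k, j in enumerate(range(sl.start, sl.stop)):
            a, b = pairs[j]
            rows.append(
                TestResult(
                    unit=f"{a}--{b}", statistic=float(stat[k]), p=float(p[k]),
                    p_adj=float(adj[k]), rejected=bool(rej[k]),
                    procedure=stage2_correction, level=stage2_level,
                )
            )
        stage2[block.name] = rows
    return stage1, stage2


def prop1_condition(alpha: float, s: int, m_i: int) -> bool:
    """Sufficient condition forcing stage-2 detection inside a significant subset.

    Under the known-sigma mean-summary model with subset-level Bonferroni
    over s subsets and within-subset Bonferroni over m_i atoms, if

        PhiInv(1 - alpha/s) >= sqrt(m_i) * PhiInv(1 - alpha/m_i)

    then every subset whose mean difference is Bonferroni-significant at
    stage 1 contains at least one atom passing the stage-2 Bonferroni
    test: were all m_i atom differences below the stage-2 critical value
    sigma sqrt(2/n) PhiInv(1 - alpha/m_i), their mean would fall below the
    stage-1 critical value, a contradiction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if s < 1 or m_i < 1:
        raise ValueError("s and m_i must be >= 1")
    lhs = stats.norm.ppf(1 - alpha / s)
    rhs = np.sqrt(m_i) * stats.norm.ppf(1 - alpha / m_i)
    return bool(lhs >= rhs)
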