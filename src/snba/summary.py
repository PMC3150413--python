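"""Per-subject, per-subnetwork summary statistics.

Each block of the connection matrix is reduced, subject by subject, to a
scalar (or short vector) that captures a contextually meaningful feature
of the subnetwork:

* ``mean_weight`` — arithmetic mean of the m_i atom weights (e.g. mean
  fiber density in the block);
* ``truncated_count`` — number of atoms whose FA-channel value exceeds a
  truncation threshold, interpreted as the number of (reliable) edges in
  the subnetwork; ``truncated_proportion`` divides by m_i;
* ``effective_mean`` — mean weight restricted to the atoms passing the FA
  truncation (0 by convention when none pass);
* ``multivariate`` — concatenation of several univariate summaries into a
  p-vector, tested jointly downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConnectionMatrix, GroupStudy, SubnetworkIndex

__all__ = [
    "SummarySpec",
    "mean_weight",
    "truncated_count",
    "truncated_proportion",
    "effective_mean",
    "summary_vector",
    "block_summaries",
]

UNIVARIATE = ("mean_weight", "truncated_count", "truncated_proportion", "effective_mean")


@dataclass(eq=True, frozen=True)
class SummarySpec:
    """Specification of a per-block summary statistic.

    ``fa_threshold`` is required for the truncated/effective variants;
    ``components`` (for ``name='multivariate'``) lists the univariate specs
    that form the p-vector. The truncation comparison is strict (>) by
    default; set ``strict=False`` for >=.
    """

    name: str = "mean_weight"
    channel: str = "density"
    fa_channel: str = "fa"
    fa_threshold: float | None = None
    strict: bool = True
    components: tuple["SummarySpec", ...] = ()

    def __post_init__(self) -> None:
        if self.name == "multivariate":
            if not self.components:
                raise ValueError("multivariate spec needs components")
            names = [c.name for c in self.components]
            if len(set(names)) < len(names):
                warnings.warn("duplicate components in multivariate summary")
            for c in self.components:
                if c.name not in UNIVARIATE:
                    raise ValueError(f"unknown component {c.name!r}")
        elif self.name not in UNIVARIATE:
            raise ValueError(f"unknown summary statistic {self.name!r}")
        if self.name in UNIVARIATE[1:] and self.fa_threshold is None:
            raise ValueError(f"{self.name} requires fa_threshold")

    @property
    def p(self) -> int:
        """Dimension of the summary vector."""
        return len(self.components) if self.name == "multivariate" else 1

    @property
    def channels(self) -> tuple[str, ...]:
        specs = self.components or (self,)
        chans = []
        for c in specs:
            chans.append(c.channel)
            if c.name in UNIVARIATE[1:]:
                chans.append(c.fa_channel)
        return tuple(dict.fromkeys(chans))


def _exceeds(fa: np.ndarray, threshold: float, strict: bool) -> np.ndarray:
    return fa > threshold if strict else fa >= threshold


def mean_weight(weights: np.ndarray) -> float:
    """Mean of the atom weights of one block for one subject."""
    weights = np.asarray(weights, float)
    if weights.size == 0:
        raise ValueError("empty block")
    return float(weights.mean())


def truncated_count(fa: np.ndarray, threshold: float, strict: bool = True) -> int:
    """Number of atoms whose FA value exceeds the truncation threshold."""
    return int(_exceeds(np.asarray(fa, float), threshold, strict).sum())


def truncated_proportion(fa: np.ndarray, threshold: float, strict: bool = True) -> float:
    fa = np.asarray(fa, float)
    if fa.size == 0:
        raise ValueError("empty block")
    return truncated_count(fa, threshold, strict) / fa.size


def effective_mean(
    weights: np.ndarray, fa: np.ndarray, threshold: float, strict: bool = True
) -> float:
    """Mean weight over atoms passing the FA truncation; 0 when none pass."""
    weights = np.asarray(weights, float)
    fa = np.asarray(fa, float)
    if weights.shape != fa.shape:
        raise ValueError("weight and FA channels have mismatched atom support")
    keep = _exceeds(fa, threshold, strict)
    if not keep.any():
        warnings.warn("no atom passes the FA truncation; effective mean set to 0")
        return 0.0
    return float(weights[keep].mean())


def _component_value(
    spec: SummarySpec, channel_values: dict[str, np.ndarray]
) -> float:
    w = channel_values.get(spec.channel)
    fa = channel_values.get(spec.fa_channel)
    try:
        if spec.name == "mean_weight":
            return mean_weight(w)
        if spec.name == "truncated_count":
            return float(truncated_count(fa, spec.fa_threshold, spec.strict))
        if spec.name == "truncated_proportion":
            return truncated_proportion(fa, spec.fa_threshold, spec.strict)
        return effective_mean(w, fa, spec.fa_threshold, spec.strict)
    except Exception as exc:
        raise ValueError(f"component {spec.name!r} failed: {exc}") from exc


def summary_vector(
    spec: SummarySpec,
    subject: dict[str, ConnectionMatrix],
    atoms: np.ndarray,
) -> np.ndarray:
    """Evaluate a summary spec for one subject on one block's atom list.

    Returns a length-p vector (p = 1 for univariate specs).
    """
    rows, cols = atoms[:, 0], atoms[:, 1]
    channel_values = {
        ch: subject[ch].values[rows, cols] for ch in spec.channels if ch in subject
    }
    specs = spec.components or (spec,)
    return np.array([_component_value(c, channel_values) for c in specs])


def block_summaries(
    study: GroupStudy, index: SubnetworkIndex, spec: SummarySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Summary arrays for both cohorts: shapes (n1, s, p) and (n2, s, p)."""
    out = []
    for subjects in (study.group1, study.group2):
        channel_mats = {
            ch: index.atom_matrix(subjects, ch) for ch in spec.channels
        }
        n = len(subjects)
        arr = np.empty((n, index.n_blocks, spec.p))
        specs = spec.components or (spec,)
        for bi, sl in enumerate(index.block_slices):
            vals = {ch: m[:, sl] for ch, m in channel_mats.items()}
            for ci, comp in enumerate(specs):
                w = vals.get(comp.channel)
                fa = vals.get(comp.fa_channel)
                if comp.name == "mean_weight":
                    arr[:, bi, ci] = w.mean(axis=1)
                elif comp.name == "truncated_count":
                    arr[:, bi, ci] = _exceeds(fa, comp.fa_threshold, comp.strict).sum(axis=1)
                elif comp.name == "truncated_proportion":
                    arr[:, bi, ci] = _exceeds(fa, comp.fa_threshold, comp.strict).mean(axis=1)
                else:  # effective_mean, row-wise with the 0 convention
                    keep = _exceeds(fa, comp.fa_threshold, comp.strict)
                    cnt = keep.sum(axis=1)
                    tot = np.where(keep, w, 0.0).sum(axis=1)
                    arr[:, bi, ci] = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
        out.append(arr)
    return out[0], out[1]
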