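"""Synthetic connectome studies with planted block effects.

Emulates the structure of a two-cohort structural-connectivity study: per
subject, an N x N symmetric fiber-density matrix (baseline weight plus
independent Gaussian noise, clipped at zero) and an FA matrix with values
in (0, 1).  Effects are planted per block: in group 2, a chosen fraction
pi of a block's atoms is shifted upward by the raw effect Delta.  Ground
truth is returned as per-atom and per-block flags so downstream analyses
can be scored.

``demo_lobe_partition`` provides an 83-ROI, 13-lobe partition mirroring
the resolution of a gyral-based cortical parcellation, giving the 91
subnetwork blocks of the application setting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import stats

from .core import (
    ConnectionMatrix,
    GroupStudy,
    Partition,
    SubnetworkIndex,
    build_subnetwork_index,
    write_connection_matrix,
    write_partition,
)

__all__ = ["PlantedEffect", "StudyTruth", "generate_study", "demo_lobe_partition", "write_study"]


@dataclass(frozen=True)
class PlantedEffect:
    """A positive mean shift delta in a fraction pi of one block's atoms."""

    block: tuple[str, str]
    pi: float
    delta: float

    def __post_init__(self) -> None:
        if not 0 < self.pi <= 1:
            raise ValueError("pi must be in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass(eq=False)
class StudyTruth:
    """Ground-truth flags aligned with a SubnetworkIndex's flat atom order."""

    index: SubnetworkIndex
    atom_flags: np.ndarray
    n_clipped: int

    @property
    def block_flags(self) -> np.ndarray:
        """A block is affected iff it contains at least one affected atom."""
        return np.array([
            bool(self.atom_flags[sl].any()) for sl in self.index.block_slices
        ])


def demo_lobe_partition() -> Partition:
    """83 ROIs in 13 lobes: six bilateral cortical lobes plus subcortical."""
    sizes = {
        "frontal": 9, "parietal": 6, "temporal": 7,
        "occipital": 5, "cingulate": 4, "insula": 3,
    }
    assignment: dict[str, str] = {}
    for hemi in ("lh", "rh"):
        for lobe, size in sizes.items():
            for k in range(size):
                assignment[f"{hemi}.{lobe}.{k + 1}"] = f"{hemi}_{lobe}"
    for k in range(15):
        assignment[f"sc.{k + 1}"] = "subcortical"
    return Partition(assignment=assignment)


def generate_study(
    partition: Partition | None = None,
    affected: list[PlantedEffect] | None = None,
    sigma: float = 1.0,
    baseline: float = 10.0,
    n1: int = 14,
    n2: int = 12,
    channels: tuple[str, ...] = ("density", "fa"),
    fa_corr: float = 0.0,
    include_diagonal_atoms: bool = False,
    seed: int | np.random.Generator = 0,
) -> tuple[GroupStudy, StudyTruth]:
    """Two cohorts of symmetric matrices with planted positive block effects.

    Group 1 atom weights are baseline + N(0, sigma^2); group 2 adds delta
    on each affected atom.  The affected atoms of a block are drawn
    uniformly without replacement (pi * m_i of them, which must be
    integral).  Negative weights are clipped to 0 and counted in the
    returned truth.  The FA channel is drawn in (0, 1) via a Gaussian
    copula; ``fa_corr`` couples it to the density noise for stress tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    partition = partition or demo_lobe_partition()
    index = build_subnetwork_index(partition, include_diagonal_atoms=include_diagonal_atoms)
    n_atoms = index.n_atoms
    labels = index.labels
    n_nodes = len(labels)

    atom_flags = np.zeros(n_atoms, bool)
    atom_delta = np.zeros(n_atoms)
    for eff in affected or []:
        bi = next(
            (i for i, b in enumerate(index.blocks)
             if b.key == eff.block or (b.group_b, b.group_a) == eff.block),
            None,
        )
        if bi is None:
            raise ValueError(f"unknown block {eff.block}")
        sl = index.block_slices[bi]
        m_i = sl.stop - sl.start
        k_i = eff.pi * m_i
        if abs(k_i - round(k_i)) > 1e-9:
            raise ValueError(f"pi * m_i = {k_i} not integral for block {eff.block}")
        chosen = rng.choice(m_i, size=int(round(k_i)), replace=False) + sl.start
        atom_flags[chosen] = True
        atom_delta[chosen] = eff.delta

    def _subject(shift: np.ndarray) -> tuple[dict[str, ConnectionMatrix], int]:
        noise = rng.standard_normal(n_atoms)
        w = baseline + sigma * noise + shift
        clipped = int((w < 0).sum())
        w = np.maximum(w, 0.0)
        subj: dict[str, ConnectionMatrix] = {}
        mat = np.zeros((n_nodes, n_nodes))
        mat[index.atom_rows, index.atom_cols] = w
        mat[index.atom_cols, index.atom_rows] = w
        if "density" in channels:
            subj["density"] = ConnectionMatrix(labels=labels, values=mat, channel="density")
        if "fa" in channels:
            z = fa_corr * noise + np.sqrt(1 - fa_corr**2) * rng.standard_normal(n_atoms)
            fa = 0.05 + 0.9 * stats.norm.cdf(z)
            fmat = np.zeros((n_nodes, n_nodes))
            fmat[index.atom_rows, index.atom_cols] = fa
            fmat[index.atom_cols, index.atom_rows] = fa
            subj["fa"] = ConnectionMatrix(labels=labels, values=fmat, channel="fa")
        return subj, clipped

    n_clipped = 0
    group1, group2 = [], []
    for _ in range(n1):
        subj, c = _subject(np.zeros(n_atoms))
        n_clipped += c
        group1.append(subj)
    for _ in range(n2):
        subj, c = _subject(atom_delta)
        n_clipped += c
        group2.append(subj)
    study = GroupStudy(group1=group1, group2=group2)
    return study, StudyTruth(index=index, atom_flags=atom_flags, n_clipped=n_clipped)


def write_study(
    study: GroupStudy,
    partition: Partition,
    outdir: str | os.PathLike,
    truth: StudyTruth | None = None,
) -> str:
    """Write matrices, partition, manifest and (optionally) ground truth.

    Returns the manifest path; the layout round-trips through
    ``core.read_study``.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, list[dict[str, str]]] = {}
    for gname, subjects in (("group1", study.group1), ("group2", study.group2)):
        entries = []
        for k, subj in enumerate(subjects):
            entry = {}
            for channel, mat in subj.items():
                rel = f"{gname}_subj{k + 1}_{channel}.csv"
                write_connection_matrix(mat, os.path.join(outdir, rel))
                entry[channel] = rel
            entries.append(entry)
        manifest[gname] = entries
    write_partition(partition, os.path.join(outdir, "partition.tsv"))
    manifest_path = os.path.join(outdir, "manifest.yaml")
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if truth is not None:
        pairs = truth.index.atom_labels()
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write("roi_a\troi_b\taffected\n")
            for (a, b), flag in zip(pairs, truth.atom_flags):
                fh.write(f"{a}\t{b}\t{int(flag)}\n")
    return manifest_path
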