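"""Data model and I/O for connection matrices, partitions, studies and results.

A connectome study consists of per-subject weighted symmetric matrices
(one per measurement channel, e.g. fiber density and FA), a partition of
the ROIs into anatomical groups (e.g. lobes), and two cohorts to compare.
The partition induces *blocks* of the connection matrix — diagonal blocks
(intra-connectivity of one group) and off-diagonal blocks (inter-connectivity
between two groups) — whose edges are the *atoms* of the analysis.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConnectionMatrix",
    "Partition",
    "Block",
    "SubnetworkIndex",
    "GroupStudy",
    "TestResult",
    "ValidationError",
    "read_connection_matrix",
    "write_connection_matrix",
    "build_subnetwork_index",
    "read_partition",
    "write_partition",
    "read_study",
    "write_results",
    "read_results",
]

DEFAULT_SYMMETRY_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when an input file or object violates the data model."""


@dataclass(eq=False)
class ConnectionMatrix:
    """One subject's N x N symmetric weighted matrix for one channel.

    The stored matrix is canonically symmetrized, ``(A + A.T) / 2``, after
    checking that the raw asymmetry does not exceed ``tol``.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    channel: str = "weight"

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @classmethod
    def from_array(
        cls,
        values: np.ndarray,
        labels: tuple[str, ...] | list[str] | None = None,
        channel: str = "weight",
        tol: float = DEFAULT_SYMMETRY_TOL,
    ) -> "ConnectionMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(f"non-square matrix of shape {values.shape}")
        n = values.shape[0]
        if labels is None:
            labels = tuple(f"ROI_{k + 1}" for k in range(n))
        else:
            labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValidationError(
                f"{len(labels)} labels for a {n}x{n} matrix"
            )
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(f"non-finite entry at ({labels[i]}, {labels[j]})")
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative entry {values[i, j]} at ({labels[i]}, {labels[j]})"
            )
        asym = np.abs(values - values.T)
        if asym.max(initial=0.0) > tol:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"asymmetry {asym[i, j]:.3g} at ({labels[i]}, {labels[j]}) "
                f"exceeds tolerance {tol:g}"
            )
        return cls(labels=labels, values=(values + values.T) / 2.0, channel=channel)


@dataclass(eq=False)
class Partition:
    """Assignment of each ROI label to a group (e.g. lobe) label.

    ``groups`` preserves a deterministic group order (first appearance by
    default); every group must be nonempty.
    """

    assignment: dict[str, str]
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValidationError("empty partition")
        seen = list(dict.fromkeys(self.assignment.values()))
        if not self.groups:
            self.groups = tuple(seen)
        else:
            self.groups = tuple(self.groups)
            missing = set(seen) - set(self.groups)
            if missing:
                raise ValidationError(f"groups {sorted(missing)} not in group list")
            empty = set(self.groups) - set(seen)
            if empty:
                raise ValidationError(f"empty groups {sorted(empty)}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self, group: str) -> list[str]:
        return [r for r, g in self.assignment.items() if g == group]


@dataclass(eq=False)
class Block:
    """A subnetwork: diagonal (group_a == group_b) or off-diagonal block."""

    group_a: str
    group_b: str
    atoms: np.ndarray  # (m_i, 2) int index pairs, i <= j

    @property
    def key(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)

    @property
    def name(self) -> str:
        return f"{self.group_a}|{self.group_b}"

    @property
    def size(self) -> int:
        return self.atoms.shape[0]

    @property
    def is_diagonal(self) -> bool:
        return self.group_a == self.group_b


@dataclass(eq=False)
class SubnetworkIndex:
    """All L(L+1)/2 blocks induced by a partition on an ordered label set.

    Atom lists are disjoint and cover every unordered ROI pair exactly once
    (plus the N self-connections when ``include_diagonal_atoms``).  The flat
    concatenation of all atoms (``atom_rows``/``atom_cols`` with per-block
    ``block_slices``) supports vectorized extraction of subject-by-atom
    weight matrices.
    """

    labels: tuple[str, ...]
    blocks: list[Block]
    include_diagonal_atoms: bool = False
    atom_rows: np.ndarray = field(init=False)
    atom_cols: np.ndarray = field(init=False)
    block_slices: list[slice] = field(init=False)

    def __post_init__(self) -> None:
        rows, cols, slices = [], [], []
        start = 0
        for b in self.blocks:
            rows.append(b.atoms[:, 0])
            cols.append(b.atoms[:, 1])
            slices.append(slice(start, start + b.size))
            start += b.size
        self.atom_rows = np.concatenate(rows) if rows else np.empty(0, int)
        self.atom_cols = np.concatenate(cols) if cols else np.empty(0, int)
        self.block_slices = slices

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_rows.size)

    @property
    def block_sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.blocks])

    def block(self, key: tuple[str, str]) -> Block:
        for b in self.blocks:
            if b.key == key or (b.group_b, b.group_a) == key:
                return b
        raise KeyError(f"no block {key}")

    def atom_labels(self) -> list[tuple[str, str]]:
        """Unordered ROI-label pair for every atom, in flat atom order."""
        return [
            (self.labels[i], self.labels[j])
            for i, j in zip(self.atom_rows, self.atom_cols)
        ]

    def atom_matrix(self, subjects: list[dict[str, ConnectionMatrix]], channel: str) -> np.ndarray:
        """Stack one channel into an (n_subjects, n_atoms) weight matrix."""
        out = np.empty((len(subjects), self.n_atoms))
        for k, subj in enumerate(subjects):
            mat = subj[channel]
            if mat.labels != self.labels:
                raise ValidationError("subject labels do not match index labels")
            out[k] = mat.values[self.atom_rows, self.atom_cols]
        return out


@dataclass(eq=False)
class GroupStudy:
    """Two cohorts of aligned per-subject channel -> matrix maps."""

    group1: list[dict[str, ConnectionMatrix]]
    group2: list[dict[str, ConnectionMatrix]]

    def __post_init__(self) -> None:
        ref = None
        for subj in self.group1 + self.group2:
            for mat in subj.values():
                if ref is None:
                    ref = mat.labels
                elif mat.labels != ref:
                    raise ValidationError("all matrices must share identical ROI labels")
        if ref is None:
            raise ValidationError("empty study")
        self.labels = ref

    @property
    def n1(self) -> int:
        return len(self.group1)

    @property
    def n2(self) -> int:
        return len(self.group2)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.group1[0].keys())


@dataclass
class TestResult:
    """Outcome of one test unit (an atom edge or a subnetwork block)."""

    unit: str
    statistic: float
    p: float
    p_adj: float
    rejected: bool
    procedure: str
    level: float


# ---------------------------------------------------------------------------
# I/O


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") and "\t" in line else ","


def read_connection_matrix(
    path: str | os.PathLike,
    channel: str = "weight",
    tol: float = DEFAULT_SYMMETRY_TOL,
) -> ConnectionMatrix:
    """Read a dense delimited matrix, with an optional ROI-label header row.

    The header is detected by attempting float conversion of the first row.
    """
    with open(path) as fh:
        first = fh.readline()
        rest = fh.read()
    sep = _sniff_delimiter(first)
    tokens = [t.strip() for t in first.strip().split(sep)]
    labels = None
    try:
        [float(t) for t in tokens]
        body = first + rest
    except ValueError:
        labels = [t for t in tokens if t != ""]
        body = rest
    rows = [r for r in body.splitlines() if r.strip()]
    data = []
    try:
        for r in rows:
            cells = [c.strip() for c in r.split(sep)]
            # tolerate a leading label column when a header row was present
            if labels is not None and len(cells) == len(labels) + 1:
                cells = cells[1:]
            data.append([float(c) for c in cells])
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    widths = {len(r) for r in data}
    if len(widths) != 1 or len(data) != widths.pop():
        raise ValidationError(f"non-square matrix in {path}")
    return ConnectionMatrix.from_array(np.array(data), labels=labels, channel=channel, tol=tol)


def write_connection_matrix(mat: ConnectionMatrix, path: str | os.PathLike) -> None:
    """Write a matrix as CSV with a header row of ROI labels."""
    with open(path, "w") as fh:
        fh.write(",".join(mat.labels) + "\n")
        for row in mat.values:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")


def read_partition(path: str | os.PathLike) -> Partition:
    """Read a two-column TSV (roi_label, group_label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["roi", "group"], dtype=str, comment="#")
    return Partition(assignment=dict(zip(df["roi"], df["group"])))


def write_partition(partition: Partition, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for roi, group in partition.assignment.items():
            fh.write(f"{roi}\t{group}\n")


def build_subnetwork_index(
    partition: Partition,
    include_diagonal_atoms: bool = False,
    labels: tuple[str, ...] | None = None,
) -> SubnetworkIndex:
    """Enumerate all L(L+1)/2 blocks and their disjoint atom lists.

    ``labels`` fixes the node order (default: partition insertion order);
    every label must be assigned to a group and vice versa.
    """
    if labels is None:
        labels = tuple(partition.assignment.keys())
    labels = tuple(labels)
    missing = set(labels) - set(partition.assignment)
    if missing:
        raise ValidationError(f"labels {sorted(missing)[:3]} missing from partition")
    extra = set(partition.assignment) - set(labels)
    if extra:
        raise ValidationError(f"partition ROIs {sorted(extra)[:3]} absent from labels")
    pos = {lab: k for k, lab in enumerate(labels)}
    group_idx: dict[str, list[int]] = {g: [] for g in partition.groups}
    for lab in labels:
        group_idx[partition.assignment[lab]].append(pos[lab])

    blocks = []
    groups = partition.groups
    for a_i, ga in enumerate(groups):
        for gb in groups[a_i:]:
            ia = group_idx[ga]
            ib = group_idx[gb]
            if ga == gb:
                pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
                if include_diagonal_atoms:
                    pairs += [(i, i) for i in ia]
            else:
                pairs = [(min(i, j), max(i, j)) for i in ia for j in ib]
            atoms = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
            blocks.append(Block(group_a=ga, group_b=gb, atoms=atoms))
    return SubnetworkIndex(labels=labels, blocks=blocks,
                           include_diagonal_atoms=include_diagonal_atoms)


def read_study(manifest_path: str | os.PathLike, tol: float = DEFAULT_SYMMETRY_TOL) -> GroupStudy:
    """Load a two-group study from a YAML/JSON manifest.

    The manifest maps ``group1``/``group2`` to lists of per-subject
    ``channel: path`` maps; relative paths resolve against the manifest.
    """
    manifest_path = os.fspath(manifest_path)
    with open(manifest_path) as fh:
        manifest = (json.load(fh) if manifest_path.endswith(".json") else yaml.safe_load(fh))
    base = os.path.dirname(os.path.abspath(manifest_path))
    groups = []
    for key in ("group1", "group2"):
        if key not in manifest:
            raise ValidationError(f"manifest missing '{key}'")
        subjects = []
        for entry in manifest[key]:
            subj = {}
            for channel, rel in entry.items():
                p = rel if os.path.isabs(rel) else os.path.join(base, rel)
                subj[channel] = read_connection_matrix(p, channel=channel, tol=tol)
            subjects.append(subj)
        groups.append(subjects)
    return GroupStudy(group1=groups[0], group2=groups[1])


RESULT_COLUMNS = ["unit", "statistic", "p", "p_adj", "rejected", "procedure", "level"]


def write_results(results: list[TestResult], path: str | os.PathLike) -> None:
    """Write a deterministic CSV results table (input order preserved)."""
    if not results:
        raise ValidationError("no results to write")
    df = pd.DataFrame(
        [(r.unit, r.statistic, r.p, r.p_adj, r.rejected, r.procedure, r.level) for r in results],
        columns=RESULT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_results(path: str | os.PathLike) -> list[TestResult]:
    df = pd.read_csv(path)
    return [
        TestResult(
            unit=str(r.unit), statistic=float(r.statistic), p=float(r.p),
            p_adj=float(r.p_adj), rejected=bool(r.rejected),
            procedure=str(r.procedure), level=float(r.level),
        )
        for r in df.itertuples()
    ]
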