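"""Repertoire-level statistics over IMGT-aligned VHH sequences.

The analyses operate on an :class:`AlignmentMatrix`: one row per fully
annotated sequence, one column per IMGT scaffold position 1-128, with '-'
for unoccupied positions.  CDR3 insertion-coded residues are excluded from
the matrix (they contribute only to CDR3 length statistics), so all rows
share the same 128 columns regardless of loop length.

Position-wise variability is quantified by Shannon entropy over the
21-symbol alphabet (20 amino acids + gap), in bits::

    H(X)  = -sum_i p(x_i) log2 p(x_i)
    NH(X) = H(X) / log2(21)            in [0, 1]

Coupling between positions uses the plug-in mutual information and its
normalized form::

    MI(X,Y)  = sum_ij p(x_i, y_j) log2 [ p(x_i, y_j) / (p(x_i) p(y_j)) ]
    NMI(X,Y) = 2 MI(X,Y) / (H(X) + H(Y))     (0 when H(X)+H(Y)=0)

Positions are grouped by hierarchical clustering with Ward's linkage on
the distance d = 1 - NMI, cutting the merge tree at a fixed height
(default 1.1; Ward heights may exceed 1 because the linkage inflates with
cluster size).  No pseudocounts, phylogenetic down-weighting or
average-product correction are applied: the estimators are the plain
empirical plug-ins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation import (
    NumberedSequence,
    cdr3_length,
    hallmark_motif,
    noncanonical_cysteines,
)
from .errors import (
    DegenerateMatrix,
    EmptyInput,
    EmptySubset,
    InvalidDistribution,
    UnknownMotif,
)
from .schemes import SCAFFOLD_POSITIONS

GAP = "-"
#: 21-symbol alphabet: 20 amino acids + gap
ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY") + (GAP,)
LOG2_21 = math.log2(len(ALPHABET))

_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}


@dataclass
class AlignmentMatrix:
    """Rectangular repertoire x IMGT-column symbol table."""

    ids: list
    columns: tuple
    data: np.ndarray  # (n_rows, n_cols) of single characters

    def __post_init__(self):
        if self.data.shape != (len(self.ids), len(self.columns)):
            raise ValueError("data shape does not match ids/columns")
        bad = set(np.unique(self.data)) - set(ALPHABET)
        if bad:
            raise ValueError(f"symbols outside the 21-letter alphabet: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    def column(self, position: int) -> np.ndarray:
        return self.data[:, self.columns.index(position)]

    def codes(self) -> np.ndarray:
        """Integer-encoded matrix over the 21-symbol alphabet."""
        lut = np.zeros(128, dtype=np.int64)
        for s, i in _SYMBOL_INDEX.items():
            lut[ord(s)] = i
        return lut[self.data.view(np.uint32).astype(np.int64) & 0x7F]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=[str(c) for c in self.columns])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "AlignmentMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str)
        cols = tuple(int(c) for c in df.columns)
        return cls(list(df.index), cols, df.to_numpy(dtype="U1"))

    def to_fasta(self, path) -> None:
        """Aligned (gapped) FASTA export of the scaffold columns."""
        with open(path, "w") as fh:
            for i, seq_id in enumerate(self.ids):
                fh.write(f">{seq_id}\n{''.join(self.data[i])}\n")


def build_alignment(seqs: Sequence[NumberedSequence]) -> AlignmentMatrix:
    """One row per sequence over the fixed 1-128 scaffold columns."""
    seqs = list(seqs)
    if not seqs:
        raise EmptyInput("no sequences to align")
    data = np.full((len(seqs), len(SCAFFOLD_POSITIONS)), GAP, dtype="U1")
    col_of = {p: j for j, p in enumerate(SCAFFOLD_POSITIONS)}
    for i, ns in enumerate(seqs):
        for r in ns.residues:
            if not r.insertion:
                aa = r.amino_acid if r.amino_acid in _SYMBOL_INDEX else GAP
                data[i, col_of[r.position]] = aa
    return AlignmentMatrix([ns.id for ns in seqs], SCAFFOLD_POSITIONS, data)


# ---------------------------------------------------------------------------
# probabilities and entropy


def column_probabilities(m: AlignmentMatrix) -> pd.DataFrame:
    """Empirical symbol frequencies (no pseudocounts); alphabet x columns."""
    if m.n == 0:
        raise EmptyInput("empty alignment")
    codes = m.codes()
    counts = np.zeros((len(ALPHABET), len(m.columns)))
    for j in range(len(m.columns)):
        counts[:, j] = np.bincount(codes[:, j], minlength=len(ALPHABET))
    probs = counts / m.n
    return pd.DataFrame(probs, index=list(ALPHABET), columns=list(m.columns))


def _check_probs(p: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise InvalidDistribution(f"probabilities sum to {p.sum():.6g}")
    return np.clip(p, 0.0, None)


def shannon_entropy(p: Iterable[float]) -> float:
    """Shannon entropy in bits; 0*log(0) taken as 0."""
    p = _check_probs(np.fromiter(p, dtype=float))
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def normalized_entropy(p: Iterable[float]) -> float:
    """Entropy scaled by log2(21), the 21-symbol ceiling; in [0, 1]."""
    return shannon_entropy(p) / LOG2_21


def entropy_profile(m: AlignmentMatrix) -> pd.DataFrame:
    """Per-column H (bits) and NH, indexed by IMGT position."""
    probs = column_probabilities(m)
    rows = []
    for col in probs.columns:
        h = shannon_entropy(probs[col].to_numpy())
        rows.append((col, h, h / LOG2_21))
    return pd.DataFrame(rows, columns=["position", "H", "NH"]).set_index("position")


# ---------------------------------------------------------------------------
# mutual information


def _column_entropy_from_codes(c: np.ndarray) -> float:
    counts = np.bincount(c)
    p = counts[counts > 0] / c.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(m: AlignmentMatrix, x: int, y: int) -> float:
    """Plug-in MI between columns ``x`` and ``y`` (IMGT positions), in bits."""
    cx = m.codes()[:, m.columns.index(x)]
    cy = m.codes()[:, m.columns.index(y)]
    return _mi_from_codes(cx, cy)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray) -> float:
    n = cx.size
    joint = np.bincount(cx * len(ALPHABET) + cy, minlength=len(ALPHABET) ** 2) / n
    hx = _column_entropy_from_codes(cx)
    hy = _column_entropy_from_codes(cy)
    nz = joint[joint > 0]
    h_joint = float(-(nz * np.log2(nz)).sum())
    return max(hx + hy - h_joint, 0.0)


def nmi(m: AlignmentMatrix, x: int, y: int) -> float:
    """Normalized mutual information 2*MI/(H(X)+H(Y)); 0 when both constant."""
    codes = m.codes()
    cx = codes[:, m.columns.index(x)]
    cy = codes[:, m.columns.index(y)]
    hx = _column_entropy_from_codes(cx)
    hy = _column_entropy_from_codes(cy)
    if hx + hy == 0.0:
        return 0.0
    return 2.0 * _mi_from_codes(cx, cy) / (hx + hy)


@dataclass
class NMIMatrix:
    """Symmetric position-coupling matrix with companion H and MI values."""

    positions: tuple
    values: np.ndarray      # NMI, symmetric, diag 1 for non-constant columns
    mi: np.ndarray          # bits
    entropies: np.ndarray   # bits, per column

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.positions, columns=self.positions)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="position")

    def mean_offdiagonal(self) -> float:
        n = len(self.positions)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


def nmi_matrix(m: AlignmentMatrix) -> NMIMatrix:
    """All-pairs NMI over the alignment columns."""
    codes = m.codes()
    ncol = len(m.columns)
    hs = np.array([_column_entropy_from_codes(codes[:, j]) for j in range(ncol)])
    mi = np.zeros((ncol, ncol))
    vals = np.zeros((ncol, ncol))
    for i in range(ncol):
        vals[i, i] = 1.0 if hs[i] > 0 else 0.0
        mi[i, i] = hs[i]
        for j in range(i + 1, ncol):
            mij = _mi_from_codes(codes[:, i], codes[:, j])
            mi[i, j] = mi[j, i] = mij
            denom = hs[i] + hs[j]
            v = 2.0 * mij / denom if denom > 0 else 0.0
            vals[i, j] = vals[j, i] = v
    return NMIMatrix(tuple(m.columns), vals, mi, hs)


# ---------------------------------------------------------------------------
# clustering of coupled positions


@dataclass
class ClusterAssignment:
    positions: tuple
    labels: dict            # position -> cluster id (1-based, ordered by smallest member)
    linkage: np.ndarray     # scipy linkage matrix
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster_id: int) -> list:
        return sorted(p for p, c in self.labels.items() if c == cluster_id)

    def cluster_of(self, position: int) -> int:
        return self.labels[position]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": list(self.positions), "cluster": [self.labels[p] for p in self.positions]}
        )


def cluster_positions(nmi_m: NMIMatrix, cutoff: float = 1.1) -> ClusterAssignment:
    """Ward-linkage flat clusters of positions on the distance 1 - NMI.

    The distance matrix is precomputed and fed to the standard Ward
    recurrence; flat clusters cut the merge tree at ``cutoff``.  Cluster
    ids are renumbered in order of each cluster's smallest member position
    so the assignment is deterministic and permutation-equivariant.
    """
    n = len(nmi_m.positions)
    if n < 2:
        raise DegenerateMatrix("need at least 2 columns to cluster")
    d = 1.0 - np.asarray(nmi_m.values, dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="ward")
    raw = fcluster(z, t=cutoff, criterion="distance")
    # stable relabeling by smallest member position
    order = {}
    for pos, lab in sorted(zip(nmi_m.positions, raw)):
        order.setdefault(lab, min(pos, order.get(lab, pos)))
    ranks = {lab: r + 1 for r, (m, lab) in enumerate(sorted((m, lab) for lab, m in order.items()))}
    labels = {pos: ranks[lab] for pos, lab in zip(nmi_m.positions, raw)}
    return ClusterAssignment(nmi_m.positions, labels, z, cutoff)


# ---------------------------------------------------------------------------
# subsets


@dataclass(frozen=True)
class SubsetSpec:
    """Selects all sequences, a Hallmark-motif subset, or the Cys subset."""

    kind: str                  # all | hallmark_motif | noncanonical_cys
    motif: str | None = None

    def __post_init__(self):
        if self.kind not in ("all", "hallmark_motif", "noncanonical_cys"):
            raise ValueError(f"unknown subset kind {self.kind!r}")
        if self.kind == "hallmark_motif":
            if not self.motif:
                raise ValueError("hallmark_motif subset requires a motif")
            bad = set(self.motif) - set("ACDEFGHIKLMNPQRSTVWY")
            if bad or len(self.motif) != 4:
                raise UnknownMotif(f"invalid Hallmark motif {self.motif!r}")

    @property
    def label(self) -> str:
        if self.kind == "all":
            return "ALL"
        if self.kind == "noncanonical_cys":
            return "Cys"
        return self.motif


def subset_filter(
    seqs: Sequence[NumberedSequence], spec: SubsetSpec
) -> tuple[list, float]:
    """Member sequences of ``spec`` and their fraction of the input."""
    seqs = list(seqs)
    if not seqs:
        raise EmptyInput("no sequences")
    if spec.kind == "all":
        members = seqs
    elif spec.kind == "hallmark_motif":
        members = [s for s in seqs if hallmark_motif(s) == spec.motif]
    else:
        members = [
            s
            for s in seqs
            if noncanonical_cysteines(s).pairing_class in ("interloop_cdr3", "intraloop_cdr3")
        ]
    return members, len(members) / len(seqs)


# ---------------------------------------------------------------------------
# logos and CDR3 lengths


def frequency_logo_matrix(m: AlignmentMatrix) -> pd.DataFrame:
    """Per-column residue frequency table (positions x 21 symbols).

    Rows are IMGT positions, columns the alphabet -- directly consumable
    by standard logo-plotting tools.
    """
    return column_probabilities(m).T


def _modal_residues(m: AlignmentMatrix) -> dict:
    """Modal symbol per column; ties broken by alphabetical residue."""
    probs = column_probabilities(m)
    order = sorted(ALPHABET)
    reordered = probs.loc[order]
    modal = {}
    for col in reordered.columns:
        v = reordered[col].to_numpy()
        modal[col] = order[int(np.argmax(v))]
    return modal


def divergent_positions(subset_m: AlignmentMatrix, all_m: AlignmentMatrix) -> list:
    """Columns whose modal residue in the subset differs from the full set."""
    if subset_m.columns != all_m.columns:
        raise ValueError("matrices must share columns")
    sub_modal = _modal_residues(subset_m)
    all_modal = _modal_residues(all_m)
    return [c for c in subset_m.columns if sub_modal[c] != all_modal[c]]


def cdr3_length_stats(
    seqs: Sequence[NumberedSequence], spec: SubsetSpec | None = None
) -> tuple[float, float, dict]:
    """Mean, SD and integer-binned histogram of CDR3 lengths in a subset."""
    if spec is not None:
        members, _ = subset_filter(seqs, spec)
    else:
        members = list(seqs)
    if not members:
        raise EmptySubset("subset has no members")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lengths = np.array([cdr3_length(s) for s in members], dtype=float)
    hist = {int(k): int(v) for k, v in zip(*np.unique(lengths.astype(int), return_counts=True))}
    return float(lengths.mean()), float(lengths.std()), hist
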