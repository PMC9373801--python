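"""Inter-position dependency analysis of predicted-site alignments.

Pairwise plug-in mutual information (bits, no bias correction) between
alignment columns, counts of dependent position pairs above a fixed MI
threshold (0.05 bits), dependency-logo-style recursive partitioning of the
alignment, and classical per-position information content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_core import encode

MI_THRESHOLD = 0.05


def _alignment_codes(alignment: list[str]) -> np.ndarray:
    if len(alignment) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("alignment sequences must have equal lengths")
    codes = np.vstack([encode(s) for s in alignment])
    if (codes == 4).any():
        raise ValueError("alignment must be N-free")
    return codes


def _mi_from_codes(codes: np.ndarray, i: int, j: int) -> float:
    joint = np.zeros((4, 4))
    np.add.at(joint, (codes[:, i], codes[:, j]), 1.0)
    joint /= codes.shape[0]
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    outer = np.outer(pi, pj)
    mask = joint > 0
    return float((joint[mask] * np.log2(joint[mask] / outer[mask])).sum())


def mutual_information(alignment: list[str], i: int, j: int) -> float:
    """Plug-in MI in bits between columns i and j (0 * log 0 = 0)."""
    codes = _alignment_codes(alignment)
    L = codes.shape[1]
    if i == j or not (0 <= i < L and 0 <= j < L):
        raise ValueError("need distinct valid positions")
    return _mi_from_codes(codes, i, j)


def mi_matrix(alignment: list[str]) -> np.ndarray:
    """Symmetric L x L matrix of pairwise MI; diagonal zero."""
    codes = _alignment_codes(alignment)
    L = codes.shape[1]
    m = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            m[i, j] = m[j, i] = _mi_from_codes(codes, i, j)
    return m


def count_dependent_pairs(matrix: np.ndarray, thr: float = MI_THRESHOLD) -> int:
    """Number of unordered position pairs with MI strictly above thr."""
    m = np.asarray(matrix)
    iu = np.triu_indices_from(m, k=1)
    return int((m[iu] > thr).sum())


def dependent_pairs(matrix: np.ndarray,
                    thr: float = MI_THRESHOLD) -> list[tuple[int, int, float]]:
    m = np.asarray(matrix)
    out = []
    for i, j in zip(*np.triu_indices_from(m, k=1)):
        if m[i, j] > thr:
            out.append((int(i), int(j), float(m[i, j])))
    out.sort(key=lambda t: -t[2])
    return out


@dataclass
class PartitionNode:
    """Node of the dependency-logo partition tree over site indices."""

    indices: np.ndarray
    split_pos: int | None = None
    children: dict[str, "PartitionNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.split_pos is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children.values())

    def to_json(self) -> dict:
        return {
            "n": int(len(self.indices)),
            "indices": [int(i) for i in self.indices],
            "split_pos": self.split_pos,
            "children": {b: c.to_json() for b, c in self.children.items()},
        }


def partition_alignment(alignment: list[str], thr: float = MI_THRESHOLD,
                        max_depth: int = 3,
                        min_size: int = 20) -> PartitionNode:
    """Recursive dependency partitioning of a site alignment.

    At each node the position with the largest total MI to all other
    positions (ties -> leftmost) splits the subset by its nucleotide;
    recursion stops when the subset's maximal pairwise MI is <= thr, the
    subset is smaller than min_size, or max_depth is reached.
    """
    codes = _alignment_codes(alignment)

    def build(indices: np.ndarray, depth: int) -> PartitionNode:
        node = PartitionNode(indices)
        if depth >= max_depth or len(indices) < min_size:
            return node
        sub = codes[indices]
        L = sub.shape[1]
        m = np.zeros((L, L))
        for i in range(L):
            for j in range(i + 1, L):
                m[i, j] = m[j, i] = _mi_from_codes(sub, i, j)
        if m.max() <= thr:
            return node
        split = int(np.argmax(m.sum(axis=1)))  # leftmost on ties via argmax
        node.split_pos = split
        for b, base in enumerate("ACGT"):
            child_idx = indices[sub[:, split] == b]
            if len(child_idx):
                node.children[base] = build(child_idx, depth + 1)
        return node

    return build(np.arange(codes.shape[0]), 0)


def logo_data(alignment: list[str]) -> pd.DataFrame:
    """Per-position letter frequencies and information content IC = 2 - H."""
    codes = _alignment_codes(alignment)
    n, L = codes.shape
    rows = []
    for j in range(L):
        f = np.bincount(codes[:, j], minlength=4) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            h = float(-np.where(f > 0, f * np.log2(f), 0.0).sum())
        rows.append({"position": j, "A": f[0], "C": f[1], "G": f[2],
                     "T": f[3], "ic_bits": 2.0 - h})
    return pd.DataFrame(rows)


def stringency_bands(hits, ladder=None) -> dict[str, list]:
    """Split hits into stringent / medium / mild ERR bands.

    stringent: ERR <= 1e-4; medium: 1e-4 < ERR <= 2.5e-4;
    mild: 2.5e-4 < ERR <= 5e-4.
    """
    if ladder is None:
        from .calibration import ERR_LADDER
        ladder = ERR_LADDER
    s, m, d = ladder["stringent"], ladder["medium"], ladder["mild"]
    bands: dict[str, list] = {"stringent": [], "medium": [], "mild": []}
    for h in hits:
        if h.err <= s:
            bands["stringent"].append(h)
        elif h.err <= m:
            bands["medium"].append(h)
        elif h.err <= d:
            bands["mild"].append(h)
    return bands
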