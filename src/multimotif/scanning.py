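"""Model-agnostic window scanning and score-level ROC arithmetic.

Every motif model in the package exposes two attributes:

``length``
    motif width L in bp;
``score_windows(codes)``
    vectorised scorer taking an ``(n, L)`` uint8 array of N-free encoded
    windows (A=0, C=1, G=2, T=3) and returning ``n`` raw scores.

This module turns that contract into sequence scanning (both strands,
forward-strand offsets, N-containing windows excluded) and into the
score-level partial-AUC computation shared by model selection, the genetic
algorithm and the evaluation layer.
"""

from __future__ import annotations

import numpy as np

from .seq_core import encode, revcomp


def window_view(codes: np.ndarray, L: int) -> np.ndarray:
    """(len-L+1, L) sliding windows over a 1-D code array."""
    if len(codes) < L:
        return np.empty((0, L), dtype=codes.dtype)
    return np.lib.stride_tricks.sliding_window_view(codes, L)


def valid_windows(codes: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """N-free windows and their 0-based offsets."""
    win = window_view(codes, L)
    if win.shape[0] == 0:
        return win, np.empty(0, dtype=np.intp)
    ok = ~(win == 4).any(axis=1)
    return win[ok], np.nonzero(ok)[0]


def scan_sequence(model, seq: str, both_strands: bool = True):
    """Score every N-free window of *seq*.

    Returns a list of ``(offset, strand, score)`` tuples; offsets always
    refer to the forward strand (for a '-' hit, the offset of the window's
    leftmost forward-strand base).
    """
    L = model.length
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < motif length {L}")
    out = []
    codes = encode(seq)
    win, offs = valid_windows(codes, L)
    if win.shape[0]:
        for o, s in zip(offs, model.score_windows(win)):
            out.append((int(o), "+", float(s)))
    if both_strands:
        rc = encode(revcomp(seq))
        win, offs = valid_windows(rc, L)
        if win.shape[0]:
            fwd_offs = len(seq) - L - offs
            for o, s in zip(fwd_offs, model.score_windows(win)):
                out.append((int(o), "-", float(s)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def best_window(model, seq: str, both_strands: bool = True):
    """(offset, strand, score, window_string) of the top-scoring window.

    Ties break toward the smaller offset, '+' before '-'. Returns None when
    no N-free window exists.
    """
    hits = scan_sequence(model, seq, both_strands)
    if not hits:
        return None
    off, strand, score = max(hits, key=lambda t: (t[2], -t[0], t[1] == "+"))
    L = model.length
    window = seq[off:off + L]
    if strand == "-":
        window = revcomp(window)
    return off, strand, score, window


def best_scores(model, seqs, both_strands: bool = True) -> np.ndarray:
    """Per-sequence max window score (both strands); -inf if unscannable."""
    L = model.length
    out = np.full(len(seqs), -np.inf)
    for i, seq in enumerate(seqs):
        if len(seq) < L:
            continue
        m = -np.inf
        for s in (seq, revcomp(seq)) if both_strands else (seq,):
            win, _ = valid_windows(encode(s), L)
            if win.shape[0]:
                m = max(m, float(model.score_windows(win).max()))
        out[i] = m
    return out


def all_window_scores(model, seqs, both_strands: bool = True) -> np.ndarray:
    """Concatenated scores of every N-free window in *seqs* (both strands)."""
    L = model.length
    chunks = []
    for seq in seqs:
        if len(seq) < L:
            continue
        for s in (seq, revcomp(seq)) if both_strands else (seq,):
            win, _ = valid_windows(encode(s), L)
            if win.shape[0]:
                chunks.append(model.score_windows(win))
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


class WindowStack:
    """Pre-encoded N-free windows of a sequence collection.

    Encoding and window extraction dominate repeated scanning of the same
    sequences by many candidate models; this caches them once.  Windows of
    both strands of one sequence form a contiguous segment, so per-sequence
    maxima reduce with ``np.maximum.reduceat``.
    """

    def __init__(self, seqs, L: int, both_strands: bool = True):
        self.L = L
        chunks = []
        sizes = []
        for seq in seqs:
            n = 0
            if len(seq) >= L:
                for s in (seq, revcomp(seq)) if both_strands else (seq,):
                    win, _ = valid_windows(encode(s), L)
                    if win.shape[0]:
                        chunks.append(win)
                        n += win.shape[0]
            sizes.append(n)
        self.windows = (np.vstack(chunks) if chunks
                        else np.empty((0, L), dtype=np.uint8))
        self.sizes = np.array(sizes)
        self.n_seqs = len(sizes)

    def all_scores(self, model) -> np.ndarray:
        if self.windows.shape[0] == 0:
            return np.empty(0)
        return model.score_windows(self.windows)

    def best_per_seq(self, model) -> np.ndarray:
        """Per-sequence max window score; -inf for unscannable sequences."""
        out = np.full(self.n_seqs, -np.inf)
        if self.windows.shape[0] == 0:
            return out
        scores = model.score_windows(self.windows)
        nz = self.sizes > 0
        starts = np.concatenate([[0], np.cumsum(self.sizes)[:-1]])
        out[nz] = np.maximum.reduceat(scores, starts[nz])
        return out


# ---------------------------------------------------------------------------
# score-level ROC / partial AUC


def roc_points(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Empirical ROC swept over the union of observed scores.

    Thresholds run strict to loose; the curve starts at (0, 0). TPR is the
    fraction of positives >= threshold, FPR the fraction of negatives >=
    threshold. Returns (fpr, tpr, thresholds) with thresholds[0] = +inf
    sentinel for the (0, 0) point.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    pos = pos[np.isfinite(pos)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("empty score set for ROC")
    thr = np.unique(np.concatenate([pos, neg]))[::-1]  # strict -> loose
    ps = np.sort(pos)
    ns = np.sort(neg)
    tpr = 1.0 - np.searchsorted(ps, thr, side="left") / len(ps)
    fpr = 1.0 - np.searchsorted(ns, thr, side="left") / len(ns)
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    thr = np.concatenate([[np.inf], thr])
    return fpr, tpr, thr


def pauc_from_points(fpr: np.ndarray, tpr: np.ndarray,
                     fpr_max: float = 1e-3) -> float:
    """Trapezoidal partial area under TPR over FPR in [0, fpr_max].

    The curve is linearly interpolated at the fpr_max cut.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    if fpr_max <= 0:
        return 0.0
    # clip the curve at fpr_max with interpolation
    inside = fpr <= fpr_max
    fx = fpr[inside]
    ty = tpr[inside]
    if fx.size and fx[-1] < fpr_max and inside.sum() < fpr.size:
        j = inside.sum()  # first point beyond the cut
        x0, x1 = fpr[j - 1], fpr[j]
        y0, y1 = tpr[j - 1], tpr[j]
        ycut = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
        fx = np.concatenate([fx, [fpr_max]])
        ty = np.concatenate([ty, [ycut]])
    if fx.size < 2:
        return 0.0
    return float(np.trapezoid(ty, fx))


def pauc_from_scores(pos_scores, neg_scores, fpr_max: float = 1e-3) -> float:
    fpr, tpr, _ = roc_points(pos_scores, neg_scores)
    return pauc_from_points(fpr, tpr, fpr_max)
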