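"""Peak scanning at ERR thresholds, Venn-style classification and pairwise
hit co-localization.

A *hit* is a window whose score passes the model's threshold at the active
stringency.  Peaks are classified by which models hit them (2^m presence
categories); for each model pair both present in a peak, the peak falls in
the overlapped subfraction when some pair of hits shares at least 1 bp in
forward-strand projected coordinates (strand-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .seq_core import SequenceSet
from .scanning import scan_sequence


@dataclass(frozen=True)
class Hit:
    model_id: str
    peak_id: str
    offset: int          # 0-based, forward strand
    strand: str
    length: int
    score: float
    err: float

    @property
    def end(self) -> int:
        return self.offset + self.length


def scan_peaks(models: dict[str, tuple], peaks: SequenceSet) -> list[Hit]:
    """Scan every peak with every model at its threshold.

    *models* maps model_id -> (model, threshold, err_map); err_map may be
    None, in which case hit ERRs are reported as NaN.  Peaks shorter than a
    model's length are skipped for that model.
    """
    hits: list[Hit] = []
    for model_id, (model, threshold, err_map) in models.items():
        for rec in peaks:
            if len(rec.seq) < model.length:
                continue
            for off, strand, score in scan_sequence(model, rec.seq):
                if score >= threshold:
                    err = err_map.err_of(score) if err_map is not None else float("nan")
                    hits.append(Hit(model_id, rec.id, off, strand,
                                    model.length, score, err))
    return hits


@dataclass
class PeakClassification:
    """Presence flags per peak and Venn category counts."""

    presence: dict[str, frozenset]          # peak_id -> set of models present
    category_counts: dict[frozenset, int]   # category -> #peaks
    model_ids: list[str]

    def marginal(self, model_id: str) -> int:
        return sum(n for cat, n in self.category_counts.items()
                   if model_id in cat)

    def covered(self) -> int:
        """Peaks hit by at least one model."""
        return sum(n for cat, n in self.category_counts.items() if cat)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for r in range(len(self.model_ids) + 1):
            for cat in combinations(self.model_ids, r):
                key = frozenset(cat)
                rows.append({
                    "category": "+".join(sorted(cat)) if cat else "(none)",
                    "count": self.category_counts.get(key, 0),
                })
        return pd.DataFrame(rows)


def classify_peaks(hits: list[Hit], model_ids: list[str],
                   peaks: SequenceSet) -> PeakClassification:
    """Partition peaks over the 2^m model-presence categories."""
    peak_ids = {rec.id for rec in peaks}
    for h in hits:
        if h.peak_id not in peak_ids:
            raise ValueError(f"hit references unknown peak {h.peak_id!r}")
    presence: dict[str, set] = {rec.id: set() for rec in peaks}
    for h in hits:
        if h.model_id in model_ids:
            presence[h.peak_id].add(h.model_id)
    frozen = {pid: frozenset(s) for pid, s in presence.items()}
    counts: dict[frozenset, int] = {}
    for s in frozen.values():
        counts[s] = counts.get(s, 0) + 1
    return PeakClassification(frozen, counts, list(model_ids))


def pairwise_overlap(hits_a: list[Hit], hits_b: list[Hit],
                     peaks: SequenceSet) -> pd.DataFrame:
    """Overlapped / non-overlapped subfractions of both-present peaks.

    A both-present peak is overlapped iff some hit of A and some hit of B
    share >= 1 bp (half-open adjacency does not count); strand-agnostic.
    """
    by_peak_a: dict[str, list[Hit]] = {}
    for h in hits_a:
        by_peak_a.setdefault(h.peak_id, []).append(h)
    by_peak_b: dict[str, list[Hit]] = {}
    for h in hits_b:
        by_peak_b.setdefault(h.peak_id, []).append(h)
    rows = []
    for rec in peaks:
        la, lb = by_peak_a.get(rec.id), by_peak_b.get(rec.id)
        if not la or not lb:
            continue
        overlapped = any(
            min(a.end, b.end) - max(a.offset, b.offset) >= 1
            for a in la for b in lb
        )
        rows.append({"peak_id": rec.id, "overlapped": overlapped})
    df = pd.DataFrame(rows, columns=["peak_id", "overlapped"])
    df.attrs["n_both"] = len(df)
    df.attrs["n_overlapped"] = int(df["overlapped"].sum()) if len(df) else 0
    return df


DEFAULT_ERR_BINS = np.array([1e-5, 5e-5, 1e-4, 2.5e-4, 5e-4, 1e-3])


def score_pair_table(hits_a: list[Hit], hits_b: list[Hit],
                     err_bins: np.ndarray = DEFAULT_ERR_BINS) -> np.ndarray:
    """2-D histogram of (ERR_A, ERR_B) over co-located hit pairs.

    Bin edges must be strictly increasing; pairs with an ERR outside the
    edges are dropped (mass outside the ladder is not of interest).
    """
    err_bins = np.asarray(err_bins, dtype=float)
    if np.any(np.diff(err_bins) <= 0):
        raise ValueError("err_bins must be strictly increasing")
    by_peak_b: dict[str, list[Hit]] = {}
    for h in hits_b:
        by_peak_b.setdefault(h.peak_id, []).append(h)
    ea, eb = [], []
    for a in hits_a:
        for b in by_peak_b.get(a.peak_id, []):
            if min(a.end, b.end) - max(a.offset, b.offset) >= 1:
                ea.append(a.err)
                eb.append(b.err)
    hist, _, _ = np.histogram2d(ea, eb, bins=[err_bins, err_bins])
    return hist


def hits_to_bed_rows(hits: list[Hit]) -> pd.DataFrame:
    """Hits as a BED6+1 table in peak-local coordinates."""
    return pd.DataFrame([
        {"chrom": h.peak_id, "start": h.offset, "end": h.end,
         "name": h.model_id, "score": h.score, "strand": h.strand,
         "err": h.err}
        for h in hits
    ], columns=["chrom", "start", "end", "name", "score", "strand", "err"])
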