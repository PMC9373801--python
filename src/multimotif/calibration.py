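"""Score -> expected recognition rate (ERR) calibration.

Every model's raw score scale is mapped to the empirical probability that a
scanned window of a genome-wide calibration set — aligned fixed-length
upstream regions of protein-coding genes — scores at least as high.  ERR
is the cross-model common currency: the stringent/medium/mild thresholds
correspond to ERRs 1e-4, 2.5e-4 and 5e-4 regardless of model family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_core import Genome, GeneModel, Interval, SeqRecord, SequenceSet, revcomp
from .scanning import all_window_scores

#: the stringency ladder: named ERR targets
ERR_LADDER = {"stringent": 1e-4, "medium": 2.5e-4, "mild": 5e-4}


def build_calibration_set(genome: Genome, genes: list[GeneModel],
                          up_len: int = 1500) -> SequenceSet:
    """Strand-oriented upstream regions of length up_len per gene.

    For a + gene at [s, e) the region is [s - up_len, s); for a - gene the
    reverse complement of [e, e + up_len).  Regions that would be clipped
    at a chromosome edge are discarded.
    """
    records = []
    for g in genes:
        iv = g.interval
        if iv.chrom not in genome:
            continue
        clen = genome.length(iv.chrom)
        if g.strand == "+":
            start, end = iv.start - up_len, iv.start
            if start < 0:
                continue
            seq = genome.fetch(Interval(iv.chrom, start, end))
        else:
            start, end = iv.end, iv.end + up_len
            if end > clen:
                continue
            seq = revcomp(genome.fetch(Interval(iv.chrom, start, end)))
        records.append(SeqRecord(g.gene_id, seq, Interval(iv.chrom, start, end)))
    if not records:
        raise ValueError("no calibration region survives edge clipping")
    return SequenceSet(records, role="calibration")


@dataclass
class ScoreERRMap:
    """Monotone map from raw score to empirical tail frequency.

    ``scores`` are the sorted distinct observed scores (ascending) and
    ``errs[i]`` = (#windows scoring >= scores[i]) / total_windows, so ERR
    is non-increasing in score.
    """

    model_id: str
    scores: np.ndarray
    errs: np.ndarray
    total_windows: int

    def __post_init__(self):
        if np.any(np.diff(self.scores) <= 0):
            raise ValueError("scores must be strictly increasing")
        if np.any(np.diff(self.errs) > 0):
            raise ValueError("ERR must be non-increasing in score")

    def err_of(self, score: float) -> float:
        """ERR of an arbitrary score: empirical P(window score >= score)."""
        i = np.searchsorted(self.scores, score, side="left")
        if i >= len(self.scores):
            return 0.0 if score > self.scores[-1] else float(self.errs[-1])
        return float(self.errs[i])

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({"score": self.scores, "err": self.errs})


def compute_err_map(model, calib: SequenceSet) -> ScoreERRMap:
    """Exact empirical tail frequencies over every N-free window, both
    strands, of the calibration set."""
    scores = all_window_scores(model, calib.sequences())
    if scores.size == 0:
        raise ValueError("zero scannable windows in the calibration set")
    uniq, counts = np.unique(scores, return_counts=True)
    # tail count of windows >= uniq[i]
    tail = counts[::-1].cumsum()[::-1]
    errs = tail / scores.size
    return ScoreERRMap(getattr(model, "model_id", "model"), uniq, errs,
                       int(scores.size))


def threshold_for_err(err_map: ScoreERRMap, err_target: float) -> float:
    """Smallest score whose ERR is <= err_target.

    Raises when even the maximum observed score is exceeded too often
    (err_target below 1/total_windows cannot be realized): use a larger
    calibration set.
    """
    if not (0 < err_target <= 1):
        raise ValueError("err_target must be in (0, 1]")
    idx = np.searchsorted(-err_map.errs, -err_target, side="left")
    # errs descending; find first index with errs[idx] <= target
    while idx < len(err_map.errs) and err_map.errs[idx] > err_target:
        idx += 1
    if idx >= len(err_map.errs):
        raise ValueError(
            f"ERR target {err_target:g} below the resolution of the "
            f"calibration set (1/{err_map.total_windows}); "
            "use a larger calibration set"
        )
    return float(err_map.scores[idx])


def thresholds_for_ladder(err_map: ScoreERRMap,
                          ladder: dict[str, float] = ERR_LADDER
                          ) -> dict[str, float]:
    return {name: threshold_for_err(err_map, q) for name, q in ladder.items()}
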