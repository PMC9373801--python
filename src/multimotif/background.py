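"""Composition- and length-matched background sampling.

For every foreground peak the sampler draws candidate intervals of the same
length uniformly from the genome (chromosome chosen proportional to length)
until either ``max_per_peak`` candidates are accepted or
``max_attempts_per_peak`` draws are exhausted.  A candidate is accepted when
its A+T fraction matches the peak's within ``at_tolerance`` (1% by default)
and it shares zero bp with every foreground peak.  Duplicated background
intervals are rejected; overlap between distinct background draws is
allowed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_core import (
    Genome,
    Interval,
    PeakSet,
    SeqRecord,
    SequenceSet,
    at_fraction,
)

logger = logging.getLogger(__name__)


@dataclass
class BackgroundConfig:
    max_per_peak: int = 5          # 5 for PWM/Markov, 10 for the LPD model
    max_attempts_per_peak: int = 500
    at_tolerance: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.max_per_peak < 1:
            raise ValueError("max_per_peak must be >= 1")
        if self.max_attempts_per_peak < self.max_per_peak:
            raise ValueError("max_attempts_per_peak must be >= max_per_peak")
        if not (0 < self.at_tolerance < 1):
            raise ValueError("at_tolerance must be in (0, 1)")


def _peaks_by_chrom(peaks: PeakSet) -> dict[str, np.ndarray]:
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v)) for c, v in by.items()}


def _overlaps_any(chrom: str, start: int, end: int,
                  fg: dict[str, np.ndarray]) -> bool:
    ivs = fg.get(chrom)
    if ivs is None:
        return False
    # sorted starts; a candidate overlaps iff some peak has start < end and end > start
    i = np.searchsorted(ivs[:, 0], end)  # peaks with start < end
    return bool(np.any(ivs[:i, 1] > start))


def sample_background(genome: Genome, peaks: PeakSet,
                      config: BackgroundConfig) -> SequenceSet:
    """Sample a background SequenceSet matched to *peaks*.

    Returns records named ``bg_<peak rank>_<k>``, each carrying its source
    interval.  Raises if no sequence at all could be accepted.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = list(genome.chromosomes)
    chrom_lens = np.array([genome.length(c) for c in chrom_names], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    fg = _peaks_by_chrom(peaks)

    records: list[SeqRecord] = []
    seen: set[tuple[str, int, int]] = set()
    zero_peaks = 0
    for iv in peaks:
        peak_seq = genome.fetch(iv)
        try:
            target_at = at_fraction(peak_seq)
        except ValueError:
            logger.warning("peak rank %s is all-N; skipped", iv.rank)
            zero_peaks += 1
            continue
        length = iv.length
        accepted = 0
        for _ in range(config.max_attempts_per_peak):
            if accepted >= config.max_per_peak:
                break
            ci = rng.choice(len(chrom_names), p=chrom_p)
            chrom = chrom_names[ci]
            max_start = genome.length(chrom) - length
            if max_start < 0:
                continue
            start = int(rng.integers(0, max_start + 1))
            end = start + length
            key = (chrom, start, end)
            if key in seen:
                continue
            if _overlaps_any(chrom, start, end, fg):
                continue
            seq = genome.chromosomes[chrom][start:end]
            try:
                cand_at = at_fraction(seq)
            except ValueError:
                continue
            if abs(cand_at - target_at) > config.at_tolerance:
                continue
            seen.add(key)
            accepted += 1
            records.append(
                SeqRecord(
                    f"bg_{iv.rank}_{accepted}",
                    seq,
                    Interval(chrom, start, end),
                )
            )
        if accepted == 0:
            zero_peaks += 1
            logger.warning(
                "peak rank %s: 0 background sequences accepted after %d attempts",
                iv.rank, config.max_attempts_per_peak,
            )
    if not records:
        raise RuntimeError("no background sequences could be sampled")
    if zero_peaks:
        logger.info("%d peaks yielded no background sequence", zero_peaks)
    return SequenceSet(records, role="background")


def background_report(fg: SequenceSet, bg: SequenceSet) -> pd.DataFrame:
    """Per-peak accepted counts and AT deltas; size ratio in ``.attrs``."""
    if not len(fg) or not len(bg):
        raise ValueError("both sets must be non-empty")
    fg_at = {r.id: at_fraction(r.seq) for r in fg}
    fg_rank = {r.id: (r.source_interval.rank if r.source_interval else None)
               for r in fg}
    rows = []
    for r in fg:
        rank = fg_rank[r.id]
        matched = [b for b in bg if b.id.startswith(f"bg_{rank}_")]
        deltas = [abs(at_fraction(b.seq) - fg_at[r.id]) for b in matched]
        rows.append({
            "peak_id": r.id,
            "rank": rank,
            "n_background": len(matched),
            "max_at_delta": max(deltas) if deltas else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs["size_ratio"] = len(bg) / len(fg)
    return df
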