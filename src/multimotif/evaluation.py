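"""2-fold odd/even cross-validation, ROC construction and pAUC selection.

A peak's test statistic is its best window score over both strands (TPR =
fraction of peaks with at least one predicted motif above threshold); the
false-positive statistic is the per-window score frequency over the whole
background set.  Model quality is the partial area under the ROC curve for
FPR <= 1e-3, the regime in which genome-wide thresholds operate; grid
selection (motif length, Markov order, LPD count) maximizes the mean pAUC
over the two folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_core import PeakSet, SequenceSet
from .scanning import all_window_scores, best_scores, pauc_from_points, roc_points

logger = logging.getLogger(__name__)

PAUC_FPR_MAX = 1e-3


def split_odd_even(peaks: PeakSet) -> tuple[PeakSet, PeakSet]:
    """Deterministic 2-fold split: fold A = odd ranks, fold B = even ranks."""
    if len(peaks) < 4:
        raise ValueError("need at least 4 ranked peaks to split")
    if any(iv.rank is None for iv in peaks):
        raise ValueError("peaks must be ranked")
    odd = [iv for iv in peaks if iv.rank % 2 == 1]
    even = [iv for iv in peaks if iv.rank % 2 == 0]
    return PeakSet(odd), PeakSet(even)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    model_id: str = ""
    fold_id: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC sweep must be monotone strict->loose")

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "fpr": self.fpr,
            "tpr": self.tpr,
        })


def roc(model, test_fg: SequenceSet, test_bg: SequenceSet,
        model_id: str | None = None, fold_id: str = "") -> ROCCurve:
    """ROC from peak best-scores (TPR) vs background window scores (FPR)."""
    if not len(test_fg) or not len(test_bg):
        raise ValueError("empty test sets")
    pos = best_scores(model, test_fg.sequences())
    neg = all_window_scores(model, test_bg.sequences())
    fpr, tpr, thr = roc_points(pos, neg)
    return ROCCurve(fpr, tpr, thr,
                    model_id=model_id or getattr(model, "model_id", ""),
                    fold_id=fold_id)


def pauc(curve: ROCCurve, fpr_max: float = PAUC_FPR_MAX) -> float:
    """Partial area under TPR over FPR in [0, fpr_max] (trapezoidal)."""
    return pauc_from_points(curve.fpr, curve.tpr, fpr_max)


@dataclass
class EvalResult:
    """Winning grid setting with its per-fold and mean pAUC plus the full
    grid table."""

    model_id: str
    params: dict
    pauc_per_fold: list[float]
    mean_pauc: float
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        lines = [f"model family : {self.model_id}",
                 f"selected     : {self.params}",
                 f"fold pAUCs   : " + ", ".join(f"{p:.3g}" for p in self.pauc_per_fold),
                 f"mean pAUC    : {self.mean_pauc:.3g}",
                 "", self.table.to_string(index=False)]
        return "\n".join(lines)


def evaluate_setting(trainer, fg_folds: tuple[SequenceSet, SequenceSet],
                     bg_folds: tuple[SequenceSet, SequenceSet],
                     fpr_max: float = PAUC_FPR_MAX) -> list[float]:
    """Train on one fold, test on the other, both ways; returns 2 pAUCs."""
    paucs = []
    for train_i, test_i in ((0, 1), (1, 0)):
        model = trainer(fg_folds[train_i], bg_folds[train_i])
        curve = roc(model, fg_folds[test_i], bg_folds[test_i],
                    fold_id=f"train{train_i}")
        paucs.append(pauc(curve, fpr_max))
    return paucs


def select_params(model_family: str, trainer_factory, grid: list[dict],
                  fg_folds, bg_folds,
                  fpr_max: float = PAUC_FPR_MAX) -> EvalResult:
    """Grid search by mean 2-fold pAUC.

    *trainer_factory(params)* returns a ``trainer(fg, bg) -> model``
    callable.  A setting whose training fails is skipped with a warning; at
    least one setting must survive.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    results = []
    for params in grid:
        try:
            paucs = evaluate_setting(trainer_factory(params), fg_folds,
                                     bg_folds, fpr_max)
        except Exception as exc:  # noqa: BLE001 - setting-level isolation
            logger.warning("setting %s failed: %s", params, exc)
            continue
        mean = float(np.mean(paucs))
        rows.append({**params, "pauc_fold0": paucs[0], "pauc_fold1": paucs[1],
                     "mean_pauc": mean})
        results.append((params, paucs, mean))
    if not results:
        raise RuntimeError("every grid setting failed")
    table = pd.DataFrame(rows)
    best_params, best_paucs, best_mean = max(results, key=lambda t: t[2])
    return EvalResult(model_family, best_params, best_paucs, best_mean, table)
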