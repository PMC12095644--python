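"""Pixel-level evaluation against reference masks.

The score is F1 = TP / (TP + (FN + FP) / 2), the harmonic mean of
precision and recall with "cell" as the positive class, computed over
pooled pixels of each image. Two empty masks agree perfectly and score
F1 = 1.0 (flagged as degenerate in batch reports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import SegmentationMask
from .exceptions import ContractError

__all__ = ["EvaluationResult", "confusion_counts", "f1_score", "batch_evaluation"]


@dataclass(frozen=True)
class EvaluationResult:
    """Pixelwise confusion counts for one mask pair."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def degenerate(self) -> bool:
        """Both masks empty: nothing positive anywhere."""
        return self.TP == 0 and self.FP == 0 and self.FN == 0

    @property
    def precision(self) -> float:
        denom = self.TP + self.FP
        return self.TP / denom if denom else 1.0

    @property
    def recall(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else 1.0

    @property
    def f1(self) -> float:
        return f1_score(self)


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)


def confusion_counts(pred, truth) -> EvaluationResult:
    """Pixelwise TP/FP/FN/TN with cell (True) as the positive class."""
    p = _as_bool(pred)
    t = _as_bool(truth)
    if p.shape != t.shape:
        raise ContractError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return EvaluationResult(TP=tp, FP=fp, FN=fn, TN=tn)


def f1_score(result: EvaluationResult) -> float:
    """F1 = TP / (TP + (FN + FP)/2); 1.0 when both masks are empty."""
    denom = result.TP + 0.5 * (result.FN + result.FP)
    if denom == 0:
        return 1.0  # perfect agreement on emptiness
    return result.TP / denom


def batch_evaluation(
    named_pairs: list[tuple[str, np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Evaluate (name, pred, truth) pairs into a tidy table.

    Returns one row per image (name, TP, FP, FN, TN, precision, recall,
    F1, degenerate) followed by a summary row with the mean and sd of F1,
    mirroring the "average F1 (S.D. = +/- ...)" reporting convention.
    """
    rows = []
    for name, pred, truth in named_pairs:
        r = confusion_counts(pred, truth)
        rows.append(
            {
                "name": name,
                "TP": r.TP,
                "FP": r.FP,
                "FN": r.FN,
                "TN": r.TN,
                "precision": r.precision,
                "recall": r.recall,
                "F1": r.f1,
                "degenerate": r.degenerate,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        f1s = df["F1"].to_numpy()
        summary = {
            "name": "summary(mean,sd)",
            "TP": df["TP"].sum(),
            "FP": df["FP"].sum(),
            "FN": df["FN"].sum(),
            "TN": df["TN"].sum(),
            "precision": df["precision"].mean(),
            "recall": df["recall"].mean(),
            "F1": f1s.mean(),
            "degenerate": bool(df["degenerate"].all()),
            "F1_sd": f1s.std(ddof=1) if len(f1s) > 1 else 0.0,
        }
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df
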