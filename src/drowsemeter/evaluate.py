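"""Segment-level scoring of pipeline output against ground truth.

An experiment is divided into ~1-minute segments in which the driver holds
one simulated drowsiness state.  The per-second FIS output is reduced to
one predicted label per segment by majority vote, with ties broken toward
the more severe label (the fail-safe direction: an alarm raised too
eagerly is cheaper than a missed drowsy driver).  Predictions are then
summarized in a 3x3 confusion matrix with per-class and total accuracy.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import CoverageError
from .fuzzy import STATES


@dataclass(frozen=True)
class SegmentResult:
    """One scored segment: its truth label, predicted label and time span."""

    index: int
    truth: str
    predicted: str
    span: Tuple[float, float]  # (start, end], seconds


@dataclass(frozen=True)
class ConfusionSummary:
    """3x3 confusion matrix (rows truth, columns predicted) with accuracies."""

    matrix: np.ndarray
    labels: Tuple[str, ...] = STATES

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.matrix)) / self.total

    @property
    def per_class_accuracy(self) -> dict:
        out = {}
        for i, lab in enumerate(self.labels):
            row = self.matrix[i].sum()
            out[lab] = float(self.matrix[i, i]) / row if row else float("nan")
        return out

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "matrix": self.matrix.tolist(),
            "per_class_accuracy": self.per_class_accuracy,
            "total_accuracy": self.accuracy,
            "n_segments": self.total,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        head = "truth \\ pred " + " ".join(f"{l:>8}" for l in self.labels)
        rows = [f"{lab:>12} " + " ".join(f"{v:8d}" for v in self.matrix[i])
                for i, lab in enumerate(self.labels)]
        acc = " ".join(f"{lab}={a:.1%}" for lab, a in self.per_class_accuracy.items())
        return "\n".join([head, *rows,
                          f"total accuracy {self.accuracy:.1%} ({acc})"])


def segments_from_truth(truth: pd.DataFrame) -> List[Tuple[int, str, float, float]]:
    """Truth spans ``(index, label, start, end)`` from a per-second track.

    Uses the explicit ``segment`` id column when present; otherwise each
    maximal run of a constant label forms one segment.  A truth row at
    second ``t`` covers the interval ``(t-1, t]``.
    """
    truth = truth.sort_values("t").reset_index(drop=True)
    if "segment" in truth.columns:
        ids = truth["segment"].to_numpy()
    else:
        lab = truth["label"].to_numpy()
        ids = np.concatenate(([0], np.cumsum(lab[1:] != lab[:-1])))
    out = []
    for idx in pd.unique(ids):
        rows = truth[ids == idx]
        out.append((int(idx), str(rows["label"].iloc[0]),
                    float(rows["t"].min() - 1.0), float(rows["t"].max())))
    return out


def segment_predictions(levels: pd.DataFrame,
                        truth: pd.DataFrame) -> List[SegmentResult]:
    """Predict one label per truth segment by per-second majority vote.

    ``levels`` needs columns ``t`` and ``state`` (Normal/Drowsy/Severe);
    the vote for the segment ``(a, b]`` uses the emissions with
    ``a < t <= b``.  Ties go to the more severe label.  A segment with no
    emission at all raises :class:`CoverageError`.
    """
    t = levels["t"].to_numpy(dtype=float)
    states = levels["state"].to_numpy()
    results = []
    for idx, label, a, b in segments_from_truth(truth):
        mask = (t > a + 1e-9) & (t <= b + 1e-9)
        if not mask.any():
            raise CoverageError(f"segment {idx} ({a:g}, {b:g}] has no per-second output")
        counts = Counter(states[mask])
        best = max(counts.values())
        # ties break toward the most severe of the winning labels
        predicted = max((s for s in STATES if counts.get(s, 0) == best),
                        key=STATES.index)
        results.append(SegmentResult(index=idx, truth=label,
                                     predicted=predicted, span=(a, b)))
    return results


def confusion(results: Sequence[SegmentResult]) -> ConfusionSummary:
    """Count a 3x3 confusion matrix (rows truth, columns predicted)."""
    if not results:
        raise CoverageError("no segment results to summarize")
    mat = np.zeros((3, 3), dtype=int)
    for r in results:
        mat[STATES.index(r.truth), STATES.index(r.predicted)] += 1
    return ConfusionSummary(matrix=mat)
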