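"""Cell-level detection scoring against ground truth.

A ground-truth cell counts as detected when a predicted patch matches it
one-to-one with intersection-over-union at least ``min_overlap`` (default
0.5), the standard cell-detection convention.  Matching is greedy by
descending IoU; cell-level segmentation accuracy is the matched fraction
of ground-truth cells, and precision the matched fraction of predictions,
so spurious patches lower precision without touching accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .partition import LabelMap


@dataclass
class MatchReport:
    n_gt: int
    n_pred: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)
    accuracy: float = 0.0
    precision: float = 0.0
    recall: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_gt": self.n_gt,
            "n_pred": self.n_pred,
            "n_matched": len(self.matches),
            "matches": [
                {"gt": g, "pred": p, "iou": o} for g, p, o in self.matches
            ],
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
        }


def _labels_array(x) -> np.ndarray:
    arr = x.labels if isinstance(x, LabelMap) else np.asarray(x)
    if arr.ndim != 2:
        raise ParameterError("label maps must be 2-D")
    return arr.astype(np.int64)


def pairwise_iou(pred: np.ndarray, gt: np.ndarray) -> dict[tuple[int, int], float]:
    """IoU for every (gt, pred) label pair that intersects."""
    both = (pred > 0) & (gt > 0)
    areas_pred = np.bincount(pred.ravel())
    areas_gt = np.bincount(gt.ravel())
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    out = {}
    for (g, p), inter in zip(pairs.T, counts):
        union = areas_gt[g] + areas_pred[p] - inter
        out[(int(g), int(p))] = float(inter / union)
    return out


def match_cells(pred, gt, min_overlap: float = 0.5) -> MatchReport:
    """Greedy one-to-one matching of predicted patches to ground-truth cells.

    Candidate pairs are sorted by descending IoU (ties broken by gt then
    pred label); pairs below ``min_overlap`` never match.  Accuracy is
    matched gt cells / n_gt; precision is matched / n_pred.
    """
    pred = _labels_array(pred)
    gt = _labels_array(gt)
    if pred.shape != gt.shape:
        raise ParameterError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    gt_ids = np.unique(gt[gt > 0])
    pred_ids = np.unique(pred[pred > 0])
    n_gt, n_pred = int(gt_ids.size), int(pred_ids.size)
    ious = pairwise_iou(pred, gt)
    order = sorted(ious.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for (g, p), iou in order:
        if iou < min_overlap:
            break
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        matches.append((g, p, iou))
    matched = len(matches)
    accuracy = matched / n_gt if n_gt else 1.0
    precision = matched / n_pred if n_pred else (1.0 if n_gt == 0 else 0.0)
    return MatchReport(
        n_gt=n_gt,
        n_pred=n_pred,
        matches=matches,
        accuracy=accuracy,
        precision=precision,
        recall=accuracy,
    )


def sequence_accuracy(reports: list[MatchReport]) -> float:
    """Unweighted mean of per-frame cell-level accuracies."""
    if not reports:
        raise ParameterError("sequence_accuracy needs at least one report")
    return float(np.mean([r.accuracy for r in reports]))
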