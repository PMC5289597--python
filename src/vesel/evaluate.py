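"""Detection quality metrics: optimal center matching, precision,
recall and the FN-based error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["MatchResult", "match_detections", "metrics"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)  # (gt_id, pred_label, dist_nm)
    precision: float = float("nan")
    recall: float = float("nan")
    error_rate_pct: float = float("nan")

    def pairs_table(self):
        return pd.DataFrame(
            self.pairs, columns=["gt_id", "pred_label", "center_dist_nm"]
        )


def metrics(tp, fp, fn):
    """precision = tp/(tp+fp); recall = tp/(tp+fn);
    error_rate_pct = 100 * fn/(tp+fn).  Undefined ratios are NaN."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    error = 100.0 * fn / (tp + fn) if tp + fn > 0 else float("nan")
    return precision, recall, error


def _pred_centers(pred):
    if len(pred) == 0:
        return np.zeros((0, 3)), []
    if isinstance(pred, np.ndarray):
        return np.asarray(pred, dtype=float), list(range(1, len(pred) + 1))
    centers = np.array([r.center_nm for r in pred], dtype=float)
    return centers, [r.label for r in pred]


def match_detections(gt, pred, max_dist_nm=None):
    """One-to-one assignment of predictions to ground truth minimizing
    total center distance among pairs within ``max_dist_nm``.

    ``pred`` is a list of VesicleRecord or an (n, 3) array of centers.
    ``max_dist_nm`` defaults to half the mean ground-truth inner
    diameter.  Unmatched predictions are FP, unmatched ground truth FN.
    """
    gt_centers = gt.centers()
    gt_ids = gt.table["id"].tolist()
    pred_centers, pred_labels = _pred_centers(pred)
    if max_dist_nm is None:
        if "inner_diameter_nm" in gt.table.columns and len(gt):
            max_dist_nm = float(gt.table["inner_diameter_nm"].mean()) / 2.0
        else:
            raise ValueError("max_dist_nm required without GT diameters")
    if max_dist_nm <= 0:
        raise ValueError("max_dist_nm must be positive")

    n_gt, n_pred = len(gt_centers), len(pred_centers)
    pairs = []
    if n_gt and n_pred:
        diff = gt_centers[:, None, :] - pred_centers[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        # disallowed pairs get a large finite cost; validated after assignment
        big = max_dist_nm * 1e6
        cost = np.where(dist <= max_dist_nm, dist, big)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if dist[r, c] <= max_dist_nm:
                pairs.append((gt_ids[r], pred_labels[c], float(dist[r, c])))
    tp = len(pairs)
    fp = n_pred - tp
    fn = n_gt - tp
    precision, recall, error = metrics(tp, fp, fn)
    return MatchResult(
        tp=tp, fp=fp, fn=fn, pairs=pairs,
        precision=precision, recall=recall, error_rate_pct=error,
    )
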