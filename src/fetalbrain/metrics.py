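"""Evaluation statistics for segmentation masks and GA regression.

Segmentation: Dice overlap, 95th-percentile symmetric Hausdorff surface
distance (mm), sensitivity (TPR) and specificity (TNR), per tissue class and
macro-averaged over the classes present.  Regression: RMSE (weeks) and the
concordance index (fraction of correctly ordered subject pairs, ties counted
half).

Conventions: Dice of two empty masks is 1.0 and of exactly one empty mask is
0.0; HD95 is undefined (None) when either mask is empty and such entries are
excluded from macro means, with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import TISSUE_LABELS

# 6-connectivity structuring element for surface extraction
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice overlap 2|X n Y| / (|X| + |Y|)."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    return 2.0 * int(np.logical_and(x, y).sum()) / (nx + ny)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Intersection over union, 2|X n Y|/|X u Y| variant exposed as |XnY|/|XuY|."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(x, y).sum()) / union


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxel coordinates (6-connectivity erosion difference)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return np.argwhere(mask & ~eroded)


def hd95(x: np.ndarray, y: np.ndarray,
         spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float | None:
    """Mean of the two directed 95th-percentile Hausdorff surface distances.

    Returns None (undefined) when either mask is empty.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if not x.any() or not y.any():
        return None
    sp = np.asarray(spacing, dtype=float)
    ax = surface_voxels(x) * sp
    ay = surface_voxels(y) * sp
    d_xy = cKDTree(ay).query(ax)[0]
    d_yx = cKDTree(ax).query(ay)[0]
    return 0.5 * (float(np.percentile(d_xy, 95)) + float(np.percentile(d_yx, 95)))


def sensitivity_specificity(x: np.ndarray, y: np.ndarray):
    """(TPR, TNR) of prediction ``y`` against truth ``x``; None when undefined."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    tp = int(np.logical_and(x, y).sum())
    fn = int(np.logical_and(x, ~y).sum())
    tn = int(np.logical_and(~x, ~y).sum())
    fp = int(np.logical_and(~x, y).sum())
    tpr = tp / (tp + fn) if (tp + fn) else None
    tnr = tn / (tn + fp) if (tn + fp) else None
    return tpr, tnr


def rmse(pred, gt) -> float:
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("length mismatch")
    if pred.size < 1:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((pred - gt) ** 2)))


def c_index(gt, pred) -> float | None:
    """Concordance over pairs with distinct truth; prediction ties count 0.5."""
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if gt.shape != pred.shape:
        raise ValueError("length mismatch")
    if gt.size < 2:
        raise ValueError("need at least two values")
    dg = gt[:, None] - gt[None, :]
    dp = pred[:, None] - pred[None, :]
    iu = np.triu_indices(gt.size, k=1)
    dg, dp = dg[iu], dp[iu]
    informative = dg != 0
    n_pairs = int(informative.sum())
    if n_pairs == 0:
        return None
    concordant = (np.sign(dg[informative]) == np.sign(dp[informative])) & (dp[informative] != 0)
    ties = dp[informative] == 0
    return float((concordant.sum() + 0.5 * ties.sum()) / n_pairs)


# ------------------------------------------------------------------ reports
@dataclass
class SegEvalReport:
    per_class: dict = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    n_undefined_hd95: int = 0

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "n_undefined_hd95": self.n_undefined_hd95,
        }


def evaluate_segmentation(truth: np.ndarray, pred: np.ndarray,
                          spacing=(1.0, 1.0, 1.0),
                          labels=TISSUE_LABELS) -> SegEvalReport:
    """One-vs-rest metrics per tissue label plus unweighted macro means."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {pred.shape}")
    report = SegEvalReport()
    for lab in labels:
        tmask = truth == lab
        pmask = pred == lab
        tpr, tnr = sensitivity_specificity(tmask, pmask)
        report.per_class[int(lab)] = {
            "dsc": dice(tmask, pmask),
            "hd95": hd95(tmask, pmask, spacing),
            "sensitivity": tpr,
            "specificity": tnr,
        }
    for key in ("dsc", "hd95", "sensitivity", "specificity"):
        vals = [m[key] for m in report.per_class.values() if m[key] is not None]
        report.macro[key] = float(np.mean(vals)) if vals else None
    report.n_undefined_hd95 = sum(
        1 for m in report.per_class.values() if m["hd95"] is None
    )
    return report


@dataclass
class RegEvalReport:
    rmse: float
    c_index: float | None

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "c_index": self.c_index}


def evaluate_regression(gt, pred) -> RegEvalReport:
    return RegEvalReport(rmse=rmse(pred, gt), c_index=c_index(gt, pred))
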