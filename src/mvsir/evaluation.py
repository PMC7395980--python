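"""Segmentation metrics: overlap scores, surface distances, and ROC analysis.

Overlap metrics compare binary volumes voxel-wise: Dice = 2|S∩G|/(|S|+|G|),
PPV = |S∩G|/|S|, SEN = |S∩G|/|G|.  Surface metrics operate on boundary
point sets (mask voxels with at least one of six face neighbours outside,
the volume border counting as outside), with centres scaled by the voxel
spacing so distances are in millimetres:

    HSD = max{ sup_x inf_y d(x,y), sup_y inf_x d(x,y) }
    ASD = 1/2 ( mean_gt min_seg d + mean_seg min_gt d )

The ROC sweep reports FPR/TPR over all distinct confidence thresholds; the
operating threshold is the point closest to the upper-left corner,
argmin sqrt(FPR^2 + (1-TPR)^2), ties resolved toward the lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError


@dataclass
class MaskPair:
    seg: np.ndarray
    gt: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.seg = np.asarray(self.seg).astype(bool)
        self.gt = np.asarray(self.gt).astype(bool)
        if self.seg.shape != self.gt.shape:
            raise ConfigurationError("segmentation and ground-truth shapes differ")


@dataclass
class MetricsReport:
    dice: float
    ppv: float
    sen: float
    hsd: float = np.nan
    asd: float = np.nan
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"dice": self.dice, "ppv": self.ppv, "sen": self.sen,
                "hsd": self.hsd, "asd": self.asd, "flags": ";".join(self.flags)}


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    optimal_threshold: float
    optimal_point: tuple[float, float]


def overlap_metrics(pair: MaskPair) -> MetricsReport:
    """Dice / PPV / SEN by voxel counting.

    Conventions: both masks empty -> Dice 1; an empty segmentation or
    ground truth makes PPV resp. SEN undefined — reported as 0 with a flag.
    """
    s, g = pair.seg, pair.gt
    inter = int(np.count_nonzero(s & g))
    ns, ng = int(np.count_nonzero(s)), int(np.count_nonzero(g))
    flags = []
    dice = 1.0 if ns + ng == 0 else 2.0 * inter / (ns + ng)
    if ns == 0:
        flags.append("empty_seg")
    if ng == 0:
        flags.append("empty_gt")
    ppv = inter / ns if ns else 0.0
    sen = inter / ng if ng else 0.0
    return MetricsReport(dice, ppv, sen, flags=tuple(flags))


def surface_points(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Centres (mm) of mask voxels with a 6-neighbour outside the mask.

    The volume border counts as outside, so a mask touching the border
    contributes its border voxels.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ConfigurationError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0)
    pts = np.argwhere(mask & ~interior).astype(float)
    return pts * np.asarray(spacing, dtype=float)


def hausdorff(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two nonempty point sets (mm)."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ConfigurationError("Hausdorff distance needs nonempty point sets")
    d_xy = cKDTree(Y).query(X)[0]
    d_yx = cKDTree(X).query(Y)[0]
    return float(max(d_xy.max(), d_yx.max()))


def asd(X: np.ndarray, Y: np.ndarray) -> float:
    """Average symmetric surface distance: half-sum of directed mean minima."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if len(X) == 0 or len(Y) == 0:
        raise ConfigurationError("ASD needs nonempty point sets")
    d_xy = cKDTree(Y).query(X)[0]
    d_yx = cKDTree(X).query(Y)[0]
    return float(0.5 * (d_xy.mean() + d_yx.mean()))


def surface_distance_metrics(pair: MaskPair) -> tuple[float, float]:
    """(HSD, ASD) in mm from the two masks' boundary point sets."""
    ps = surface_points(pair.seg, pair.spacing)
    pg = surface_points(pair.gt, pair.spacing)
    return hausdorff(ps, pg), asd(ps, pg)


def evaluate_pair(seg: np.ndarray, gt: np.ndarray,
                  spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """Full per-case report; surface metrics are NaN-flagged when a mask is empty."""
    pair = MaskPair(seg, gt, spacing)
    rep = overlap_metrics(pair)
    if pair.seg.any() and pair.gt.any():
        rep.hsd, rep.asd = surface_distance_metrics(pair)
    else:
        rep.flags = tuple(list(rep.flags) + ["no_surface_metrics"])
    return rep


def roc_optimal_threshold(confidence, gt) -> ROCCurve:
    """ROC over all distinct thresholds + closest-to-upper-left threshold.

    ``confidence`` and ``gt`` may be a PredictionVolume / mask pair or plain
    arrays; both classes must be present in ``gt``.
    """
    conf = getattr(confidence, "confidence", confidence)
    scores = np.asarray(conf, dtype=float).ravel()
    labels = np.asarray(getattr(gt, "mask", gt)).astype(bool).ravel()
    if scores.shape != labels.shape:
        raise ConfigurationError("confidence and ground truth sizes differ")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("ROC needs both classes in the ground truth")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp = np.cumsum(labels[order])
    fp = np.cumsum(~labels[order])
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tpr = tp[distinct] / n_pos
    fpr = fp[distinct] / n_neg
    thresholds = s_sorted[distinct]
    # prepend the all-negative operating point
    tpr = np.r_[0.0, tpr]
    fpr = np.r_[0.0, fpr]
    thresholds = np.r_[thresholds[0] + 1.0, thresholds]
    auc = float(np.trapezoid(tpr, fpr))
    dist = np.hypot(fpr, 1.0 - tpr)
    tied = np.nonzero(dist == dist.min())[0]
    best = tied[np.argmin(thresholds[tied])]
    return ROCCurve(thresholds, fpr, tpr, auc,
                    float(thresholds[best]), (float(fpr[best]), float(tpr[best])))


def aggregate_report(reports: dict[str, MetricsReport] | list[MetricsReport]) -> pd.DataFrame:
    """Per-case table with the column layout ASD, HSD, Dice, PPV, SEN."""
    if isinstance(reports, dict):
        rows = {k: v.as_dict() for k, v in reports.items()}
        df = pd.DataFrame.from_dict(rows, orient="index")
    else:
        df = pd.DataFrame([r.as_dict() for r in reports])
    return df[["asd", "hsd", "dice", "ppv", "sen", "flags"]].rename(
        columns={"asd": "ASD", "hsd": "HSD", "dice": "Dice",
                 "ppv": "PPV", "sen": "SEN"})


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd summary of an aggregate table's numeric columns."""
    num = df[["ASD", "HSD", "Dice", "PPV", "SEN"]]
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
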