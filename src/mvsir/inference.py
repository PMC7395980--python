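"""Per-voxel prediction over a nodule cube and 3D mask reconstruction.

Every evaluated voxel of the padded cube gets the model probability of its
six patches; probabilities are reassembled by recorded position into a
confidence volume, thresholded, and exported.  A stride (scalar or per-axis)
evaluates a subgrid only and fills the rest by nearest neighbour — a
desk-scale shortcut that is logged and recorded in the result.

The SH source at inference is the provided consensus ROI (semi-automatic
operation: a reader outline exists for the test nodule, as in the source
protocol).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .labeling import CenterSample
from .patches import DEFAULT_PATCH_SIZE, build_patch_streams
from .preprocess import NoduleCube, VolumeImage, save_volume

logger = logging.getLogger(__name__)


@dataclass
class PredictionVolume:
    """Per-voxel confidence aligned to a cube.

    ``scored`` marks voxels the model actually evaluated; with stride > 1
    the remaining confidences are nearest-neighbour copies of scored ones.
    """

    confidence: np.ndarray
    scored: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stride: tuple[int, int, int] = (1, 1, 1)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    threshold: float
    provenance: dict = field(default_factory=dict)


class ConstantModel:
    """Stub returning a fixed probability (pipeline plumbing checks)."""

    def __init__(self, p: float):
        self.p = float(p)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = np.full(len(X), self.p)
        return np.column_stack([1 - p, p])


class ShOracleModel:
    """Stub reading the axial SH centre pixel — the ground-truth probe.

    Returns the consensus-mask value at each centre, so a pipeline run with
    it must reproduce the ROI exactly; any discrepancy is a plumbing bug,
    independent of learning.
    """

    def __init__(self, patch_size: int = DEFAULT_PATCH_SIZE):
        self.mid = patch_size // 2

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = np.asarray(X)[:, 1, self.mid, self.mid].astype(float)
        return np.column_stack([1 - p, p])


def _as_stride(stride) -> tuple[int, int, int]:
    if np.isscalar(stride):
        stride = (int(stride),) * 3
    stride = tuple(int(s) for s in stride)
    if len(stride) != 3 or any(s < 1 for s in stride):
        raise ConfigurationError("stride must be a positive int or triple")
    return stride


def predict_cube(model, cube: NoduleCube, stride=1,
                 size: int = DEFAULT_PATCH_SIZE, batch_size: int = 512,
                 fill="edge", vh_normalize: bool = False) -> PredictionVolume:
    """Score every (subgrid) voxel of the cube with the model.

    ``model`` needs a ``predict_proba((n, 6, size, size)) -> (n, 2)``; the
    six patch streams per voxel are built exactly as in training.
    """
    stride = _as_stride(stride)
    shape = cube.shape
    axes = [np.arange(0, n, s) for n, s in zip(shape, stride)]
    if stride != (1, 1, 1):
        logger.info("stride %s: scoring %d of %d voxels, nearest-neighbour fill",
                    stride, np.prod([len(a) for a in axes]), int(np.prod(shape)))
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    sub = np.empty(len(centers), dtype=np.float64)
    for lo in range(0, len(centers), batch_size):
        chunk = centers[lo:lo + batch_size]
        samples = [CenterSample(tuple(int(v) for v in c), 0, int(c[0]))
                   for c in chunk]
        streams = build_patch_streams(cube, samples, size=size, fill=fill,
                                      vh_normalize=vh_normalize)
        proba = np.asarray(model.predict_proba(streams.as_array()))[:, 1]
        if np.any((proba < 0) | (proba > 1)):
            raise ConfigurationError("model probabilities outside [0, 1]")
        sub[lo:lo + batch_size] = proba
    sub = sub.reshape([len(a) for a in axes])
    # nearest evaluated subgrid index per full-grid coordinate
    nearest = [np.clip(np.round(np.arange(n) / s).astype(int), 0, len(a) - 1)
               for n, s, a in zip(shape, stride, axes)]
    confidence = sub[np.ix_(*nearest)]
    scored = np.zeros(shape, dtype=bool)
    scored[np.ix_(*axes)] = True
    return PredictionVolume(confidence, scored, spacing=cube.spacing, stride=stride)


def binarize(pred: PredictionVolume, threshold: float,
             provenance: dict | None = None) -> SegmentationResult:
    """Confidence >= threshold, with the voxel count recorded."""
    if not 0 < threshold < 1:
        raise ConfigurationError("threshold must lie strictly in (0, 1)")
    mask = pred.confidence >= threshold
    prov = dict(provenance or {})
    prov["mask_voxels"] = int(mask.sum())
    prov["stride"] = list(pred.stride)
    return SegmentationResult(mask, float(threshold), prov)


def reconstruct_export(result: SegmentationResult, pred: PredictionVolume,
                       cube: NoduleCube, out_dir) -> dict[str, Path]:
    """Write confidence + mask NIfTI (source coordinates via the cube offset)
    and a per-slice voxel-count CSV."""
    if result.mask.shape != cube.shape or pred.confidence.shape != cube.shape:
        raise ConfigurationError("result / prediction shapes differ from the cube")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    origin = tuple(o * s for o, s in zip(cube.offset, cube.spacing))
    paths = {
        "confidence": out_dir / "confidence.nii.gz",
        "mask": out_dir / "mask.nii.gz",
        "slice_counts": out_dir / "slice_counts.csv",
        "summary": out_dir / "summary.json",
    }
    save_volume(VolumeImage(pred.confidence, cube.spacing, origin),
                paths["confidence"])
    save_volume(VolumeImage(result.mask.astype(np.uint8), cube.spacing, origin),
                paths["mask"])
    counts = pd.DataFrame({
        "slice": np.arange(cube.shape[0]) + cube.offset[0],
        "mask_voxels": result.mask.sum(axis=(1, 2)),
        "roi_voxels": np.asarray(cube.consensus_mask).sum(axis=(1, 2)),
    })
    counts.to_csv(paths["slice_counts"], index=False)
    summary = {"threshold": result.threshold, "offset": list(cube.offset),
               "provenance": result.provenance}
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return paths
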