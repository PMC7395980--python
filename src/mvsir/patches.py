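"""30x30 multi-view VH / SH patch extraction around sampled centres.

Every centre voxel yields six patches: the intensity (voxel heterogeneity,
VH) and binary shape (shape heterogeneity, SH) windows of the axial
(fixed z), coronal (fixed y) and sagittal (fixed x) planes through it.  The
window spans [c - size//2, c + size - size//2 - 1] per in-plane axis, so the
centre voxel sits at patch index size//2; out-of-cube pixels are filled by
edge replication (a constant fill is available).  VH samples the cube
intensities (optionally min-max rescaled per cube); SH samples the
consensus mask and is strictly binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .labeling import CenterSample
from .network import STREAM_ORDER
from .preprocess import rescale_intensity

VIEWS = ("axial", "coronal", "sagittal")
FEATURES = ("VH", "SH")
DEFAULT_PATCH_SIZE = 30

#: which cube axis each view holds fixed, and the two in-plane axes
_VIEW_AXES = {"axial": (0, 1, 2), "coronal": (1, 0, 2), "sagittal": (2, 0, 1)}


@dataclass
class PatchRecord:
    pixels: np.ndarray
    view: str
    feature: str
    center: tuple[int, int, int]
    label: int | None = None


@dataclass
class PatchStreams:
    """Six aligned patch streams sharing one centre ordering and label vector.

    ``data`` has shape (n, 6, size, size), stream axis ordered as
    :data:`~mvsir.network.STREAM_ORDER` (axial-VH, axial-SH, coronal-VH,
    coronal-SH, sagittal-VH, sagittal-SH).
    """

    data: np.ndarray
    labels: np.ndarray
    centers: np.ndarray  # (n, 3) int, (z, y, x)
    patch_size: int = DEFAULT_PATCH_SIZE
    fill: str | float = "edge"
    vh_normalized: bool = False

    def __len__(self) -> int:
        return len(self.labels)

    def stream(self, name: str) -> np.ndarray:
        return self.data[:, STREAM_ORDER.index(name)]

    def as_array(self) -> np.ndarray:
        return self.data

    def save(self, path) -> None:
        np.savez_compressed(
            path, data=self.data.astype(np.float32), labels=self.labels,
            centers=self.centers,
            meta=np.array([self.patch_size, int(self.vh_normalized)]),
            fill=np.array(str(self.fill)))

    @classmethod
    def load(cls, path) -> "PatchStreams":
        with np.load(path) as z:
            meta = z["meta"]
            fill_s = str(z["fill"])
            fill: str | float = fill_s if fill_s == "edge" else float(fill_s)
            return cls(z["data"], z["labels"], z["centers"],
                       patch_size=int(meta[0]), fill=fill,
                       vh_normalized=bool(meta[1]))


def _window(plane: np.ndarray, row: int, col: int, size: int,
            fill: str | float) -> np.ndarray:
    half = size // 2
    rows = np.arange(row - half, row - half + size)
    cols = np.arange(col - half, col - half + size)
    if fill == "edge":
        r = np.clip(rows, 0, plane.shape[0] - 1)
        c = np.clip(cols, 0, plane.shape[1] - 1)
        return plane[np.ix_(r, c)]
    out = np.full((size, size), float(fill), dtype=plane.dtype)
    rv = (rows >= 0) & (rows < plane.shape[0])
    cv = (cols >= 0) & (cols < plane.shape[1])
    out[np.ix_(rv, cv)] = plane[np.ix_(rows[rv], cols[cv])]
    return out


def _extract(grid: np.ndarray, center, view: str, size: int,
             fill: str | float) -> np.ndarray:
    if view not in VIEWS:
        raise ConfigurationError(f"unknown view {view!r}; expected one of {VIEWS}")
    z, y, x = (int(c) for c in center)
    if not all(0 <= c < n for c, n in zip((z, y, x), grid.shape)):
        raise ConfigurationError(f"center {center} outside the cube {grid.shape}")
    fixed, a1, a2 = _VIEW_AXES[view]
    plane = np.take(grid, (z, y, x)[fixed], axis=fixed)
    row, col = (z, y, x)[a1], (z, y, x)[a2]
    return _window(plane, row, col, size, fill)


def extract_vh_patch(cube, center, view: str, size: int = DEFAULT_PATCH_SIZE,
                     fill: str | float = "edge") -> PatchRecord:
    """Intensity patch of the orthogonal plane through ``center``."""
    return PatchRecord(_extract(np.asarray(cube.data, dtype=float), center,
                                view, size, fill), view, "VH", tuple(center))


def extract_sh_patch(cube, center, view: str, size: int = DEFAULT_PATCH_SIZE,
                     fill: str | float = "edge") -> PatchRecord:
    """Binary shape patch sampling the consensus mask; pixels are {0, 1}."""
    mask = np.asarray(cube.consensus_mask).astype(np.uint8)
    fill_v = fill if fill == "edge" else float(np.clip(float(fill), 0, 1))
    return PatchRecord(_extract(mask, center, view, size, fill_v),
                       view, "SH", tuple(center))


def build_patch_streams(cube, centers: list[CenterSample],
                        size: int = DEFAULT_PATCH_SIZE,
                        fill: str | float = "edge",
                        vh_normalize: bool = False) -> PatchStreams:
    """Six patches per centre in the fixed stream order, labels carried over."""
    vh_grid = np.asarray(cube.data, dtype=float)
    if vh_normalize:
        vh_grid = rescale_intensity(vh_grid)
    sh_grid = np.asarray(cube.consensus_mask).astype(float)
    n = len(centers)
    data = np.empty((n, len(STREAM_ORDER), size, size), dtype=np.float32)
    labels = np.empty(n, dtype=np.int8)
    ctrs = np.empty((n, 3), dtype=np.int32)
    for i, cs in enumerate(centers):
        for j, name in enumerate(STREAM_ORDER):
            view, feature = name.split("-")
            grid = vh_grid if feature == "VH" else sh_grid
            data[i, j] = _extract(grid, cs.center, view, size, fill)
        labels[i] = cs.label
        ctrs[i] = cs.center
    return PatchStreams(data, labels, ctrs, patch_size=size, fill=fill,
                        vh_normalized=vh_normalize)
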