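"""Volume resampling, multi-reader consensus fusion, and nodule-cube cropping.

CT volumes are resampled to isotropic 1 mm voxels (trilinear interpolation,
output length per axis ``round(n * s_in / s_out)``).  The four readers'
slice contours are rasterized with the shared ray-casting inside test and
fused per voxel by majority vote (mean reader vote >= 0.5, ties toward
inclusion).  The nodule cube is the consensus bounding box expanded by a
10-voxel pad on every face (clipped at the volume border, with the actual
per-face pad recorded) — the pad supplies the negative, non-nodule tissue
that balances the training classes.

Axis order is (z, y, x) everywhere; voxel centres sit at integer indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .labeling import SliceAnnotation, rasterize_polygon

DEFAULT_PAD = 10


@dataclass
class VolumeImage:
    """A 3D scalar grid with per-axis voxel spacing in mm, axis order (z,y,x)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError("volume data must be 3D (z, y, x)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be three positive mm values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class NoduleCube:
    """Isotropic nodule crop: intensities + consensus mask + crop bookkeeping.

    ``offset`` maps cube index (0,0,0) back to the source volume;
    ``pad_faces`` records the achieved pad per axis as (low, high) pairs
    (smaller than ``pad`` only where the crop hit the volume border).
    """

    data: np.ndarray
    consensus_mask: np.ndarray
    pad: int
    offset: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad_faces: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.consensus_mask = np.asarray(self.consensus_mask).astype(bool)
        if self.data.shape != self.consensus_mask.shape:
            raise ConfigurationError("data and consensus mask shapes differ")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def resample_isotropic(vol: VolumeImage,
                       target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       order: int = 1) -> VolumeImage:
    """Resample to ``target_spacing`` preserving physical extent.

    Output length per axis is round(n * s_in / s_out); intensities are
    interpolated trilinearly (``order=1``; use 0 for masks).
    """
    target = tuple(float(t) for t in target_spacing)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ConfigurationError("target spacing must be three positive mm values")
    if target == vol.spacing:
        return VolumeImage(vol.data.copy(), vol.spacing, vol.origin)
    new_shape = tuple(max(1, int(round(n * s / t)))
                      for n, s, t in zip(vol.shape, vol.spacing, target))
    grids = np.meshgrid(*[np.arange(n) * t / s
                          for n, s, t in zip(new_shape, vol.spacing, target)],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    out = ndimage.map_coordinates(vol.data.astype(float), coords, order=order,
                                  mode="nearest").reshape(new_shape)
    return VolumeImage(out, target, vol.origin)


def _check_simple(vertices: np.ndarray, reader_id: int, slice_index: int) -> None:
    """Reject self-intersecting contours (naive segment-pair test, n is small)."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    segs = [(v[i], v[(i + 1) % n]) for i in range(n)]

    def _cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def _intersect(p, q, r, s):
        d1 = _cross2(q - p, r - p)
        d2 = _cross2(q - p, s - p)
        d3 = _cross2(s - r, p - r)
        d4 = _cross2(s - r, q - r)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the closing edge
            if _intersect(*segs[i], *segs[j]):
                raise ConfigurationError(
                    f"self-intersecting polygon (reader {reader_id}, "
                    f"slice {slice_index})")


def consensus_mask(annotations: list[SliceAnnotation],
                   grid_shape: tuple[int, int, int],
                   n_readers: int | None = None) -> np.ndarray:
    """Per-voxel majority vote over the readers' rasterized contours.

    Each reader's contours are rasterized with the shared ray-casting test;
    a voxel is consensus-positive when the mean reader vote is >= 0.5 (ties
    toward inclusion).  ``n_readers`` defaults to the number of distinct
    reader ids present.
    """
    if not annotations:
        raise ConfigurationError("empty annotation set")
    readers = sorted({a.reader_id for a in annotations})
    if n_readers is None:
        n_readers = len(readers)
    votes = np.zeros(grid_shape, dtype=np.int32)
    for rid in readers:
        reader_mask = np.zeros(grid_shape, dtype=bool)
        for ann in annotations:
            if ann.reader_id != rid:
                continue
            if not 0 <= ann.slice_index < grid_shape[0]:
                raise ConfigurationError(
                    f"slice index {ann.slice_index} outside grid (reader {rid})")
            _check_simple(ann.vertices, rid, ann.slice_index)
            reader_mask[ann.slice_index] |= rasterize_polygon(
                ann.vertices, grid_shape[1:])
        votes += reader_mask
    return votes * 2 >= n_readers  # mean >= 0.5, integer arithmetic, ties in


def extract_cube(vol: VolumeImage, mask: np.ndarray, pad: int = DEFAULT_PAD) -> NoduleCube:
    """Crop the mask bounding box expanded by ``pad`` voxels per face."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.shape:
        raise ConfigurationError("mask shape differs from volume shape")
    if not mask.any():
        raise ConfigurationError("cannot extract a cube from an empty mask")
    if pad < 0:
        raise ConfigurationError("pad must be >= 0")
    idx = np.argwhere(mask)
    lo_box, hi_box = idx.min(axis=0), idx.max(axis=0)
    lo = np.maximum(lo_box - pad, 0)
    hi = np.minimum(hi_box + pad, np.array(vol.shape) - 1)
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    pad_faces = tuple((int(lb - a), int(b - hb))
                      for a, b, lb, hb in zip(lo, hi, lo_box, hi_box))
    return NoduleCube(vol.data[sl].copy(), mask[sl].copy(), pad=pad,
                      offset=tuple(int(a) for a in lo), spacing=vol.spacing,
                      pad_faces=pad_faces)


def rescale_intensity(data: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1] (constant input maps to 0)."""
    data = np.asarray(data, dtype=float)
    lo, hi = data.min(), data.max()
    if hi == lo:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


# --- NIfTI / JSON I/O ----------------------------------------------------

def _affine(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: VolumeImage, path) -> None:
    """Write a NIfTI file; array axis order (z, y, x), zooms = spacing."""
    import nibabel as nib
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32),
                          _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_volume(path) -> VolumeImage:
    import nibabel as nib
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VolumeImage(np.asarray(img.dataobj), spacing, origin)


def save_cube(cube: NoduleCube, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(VolumeImage(cube.data, cube.spacing), out_dir / "cube.nii.gz")
    save_volume(VolumeImage(cube.consensus_mask.astype(np.uint8), cube.spacing),
                out_dir / "consensus_mask.nii.gz")
    sidecar = {
        "pad": cube.pad,
        "pad_faces": [list(p) for p in cube.pad_faces],
        "offset": list(cube.offset),
        "spacing": list(cube.spacing),
        "axis_order": "zyx",
    }
    (out_dir / "cube.json").write_text(json.dumps(sidecar, indent=2))


def load_cube(out_dir) -> NoduleCube:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "cube.json").read_text())
    data = load_volume(out_dir / "cube.nii.gz")
    mask = load_volume(out_dir / "consensus_mask.nii.gz")
    return NoduleCube(data.data, mask.data > 0.5, pad=meta["pad"],
                      offset=tuple(meta["offset"]), spacing=tuple(meta["spacing"]),
                      pad_faces=tuple(tuple(p) for p in meta["pad_faces"]))
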