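"""Synthetic CT nodule phantoms with analytic ground truth and reader contours.

The phantom is a (possibly bumpy) ellipsoid of raised intensity in a uniform
low-intensity background with additive i.i.d. Gaussian noise — a deliberately
minimal stand-in for a solid pulmonary nodule in lung parenchyma.  Its
surface is star-convex about the nodule centre:

    inside(p)  <=>  rho(p) <= 1 + b * g(u),      rho = ||(p - c) / radii||

where ``u`` is the direction of ``p - c``, ``b`` the bumpiness amplitude
(< 1) and ``g`` a smooth random angular field normalised to [-1, 1], drawn
deterministically from the seed.  Each axial slice that intersects the shape
gets one closed polygon per simulated reader whose vertices lie exactly on
the analytic boundary, with optional per-vertex radial jitter emulating
inter-reader variability.

The ground-truth mask is the rasterization of the noiseless contours with
the shared ray-casting inside test, so labels, consensus masks and ground
truth all use one geometry definition.

Default parameters model a small solid nodule: ~12 x 11 mm in-plane,
three axial slices thick, 840 HU contrast over lung background, sigma = 20
HU noise, four readers with 0.3 mm contour jitter.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .labeling import SliceAnnotation, rasterize_polygon
from .preprocess import DEFAULT_PAD, VolumeImage, save_volume

_N_LOBES = 8  # random angular lobes building the bumpiness field


@dataclass
class PhantomParams:
    grid_shape: tuple[int, int, int] = (39, 63, 63)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    nodule_center: tuple[float, float, float] | None = None  # default: grid centre
    radii: tuple[float, float, float] = (1.8, 6.0, 5.5)  # mm semi-axes (z, y, x)
    radial_bumpiness: float = 0.12
    nodule_intensity: float = 40.0
    background_intensity: float = -800.0
    noise_sigma: float = 20.0
    n_readers: int = 4
    reader_jitter: float = 0.3  # mm, radial, per vertex
    n_vertices: int = 64  # per slice contour
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be three positive integers")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be three positive mm values")
        if self.nodule_center is None:
            self.nodule_center = tuple((n - 1) / 2.0 for n in self.grid_shape)
        self.nodule_center = tuple(float(c) for c in self.nodule_center)
        self.radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in self.radii):
            raise ConfigurationError("radii must be positive")
        if not 0 <= self.radial_bumpiness < 1:
            raise ConfigurationError("radial_bumpiness must lie in [0, 1)")
        if self.n_readers < 1:
            raise ConfigurationError("n_readers must be >= 1")
        if self.reader_jitter < 0 or self.noise_sigma < 0:
            raise ConfigurationError("jitter and noise must be >= 0")
        if self.n_vertices < 16:
            raise ConfigurationError("contours need at least 16 vertices")
        # the nodule plus the downstream 10-voxel pad must fit in the grid
        max_r = max(self.radii) * (1 + self.radial_bumpiness)
        for c, n, s in zip(self.nodule_center, self.grid_shape, self.spacing):
            if c * s - max_r < -0.5 * s or c * s + max_r > (n - 0.5) * s:
                raise ConfigurationError("nodule is not fully inside the grid")


@dataclass
class PhantomCase:
    volume: VolumeImage
    gt_mask: np.ndarray
    annotations: list[SliceAnnotation]
    params: PhantomParams


class _BumpyEllipsoid:
    """The analytic star-convex shape: predicate + per-slice boundary polygons."""

    def __init__(self, params: PhantomParams):
        self.p = params
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x5A]))
        v = rng.standard_normal((_N_LOBES, 3))
        self.lobes = v / np.linalg.norm(v, axis=1, keepdims=True)
        self.coeffs = rng.standard_normal(_N_LOBES)
        # normalise the angular field to [-1, 1] over a dense direction sample
        if params.radial_bumpiness > 0:
            u = rng.standard_normal((2048, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            raw = self._raw_field(u)
            self._shift = raw.mean()
            self._scale = np.abs(raw - self._shift).max() or 1.0
        else:
            self._shift, self._scale = 0.0, 1.0

    def _raw_field(self, u: np.ndarray) -> np.ndarray:
        return (self.coeffs * (u @ self.lobes.T) ** 2).sum(axis=1)

    def _field(self, u: np.ndarray) -> np.ndarray:
        return (self._raw_field(u) - self._shift) / self._scale

    def signed(self, pts_mm: np.ndarray) -> np.ndarray:
        """rho - (1 + b*g); negative or zero means inside.  pts in mm (z,y,x)."""
        p = self.p
        center = np.array(p.nodule_center) * np.array(p.spacing)
        d = np.atleast_2d(pts_mm) - center
        rho = np.linalg.norm(d / np.array(p.radii), axis=1)
        if p.radial_bumpiness == 0:
            return rho - 1.0
        norm = np.linalg.norm(d, axis=1)
        u = np.divide(d, norm[:, None], out=np.zeros_like(d), where=norm[:, None] > 0)
        return rho - (1.0 + p.radial_bumpiness * self._field(u))

    def slice_polygon(self, z: int) -> np.ndarray | None:
        """Boundary polygon (continuous (y, x) voxel coords) on axial slice z.

        Vertices lie exactly on the analytic surface, found per polar angle
        by a coarse scan plus bisection along the in-plane ray from the
        projected centre.  Returns None when the slice misses the shape.
        """
        p = self.p
        sz, sy, sx = p.spacing
        cz, cy, cx = p.nodule_center
        z_mm = z * sz
        center_pt = np.array([[z_mm, cy * sy, cx * sx]])
        if self.signed(center_pt)[0] > 0:
            return None
        t_max = max(p.radii) * (1 + p.radial_bumpiness) + 1.0
        angles = np.linspace(0, 2 * np.pi, p.n_vertices, endpoint=False)
        dirs = np.column_stack([np.cos(angles), np.sin(angles)])  # (y, x) mm

        def pts_at(t):  # t: (n_vertices,) radii in mm
            return np.column_stack([np.full(len(angles), z_mm),
                                    cy * sy + t * dirs[:, 0],
                                    cx * sx + t * dirs[:, 1]])

        # coarse scan outward for the last inside radius per angle
        ts = np.linspace(0, t_max, 96)
        inside = np.stack([self.signed(pts_at(np.full(len(angles), t))) <= 0
                           for t in ts])  # (96, n_vertices)
        last_in = inside.shape[0] - 1 - np.argmax(inside[::-1], axis=0)
        lo = ts[last_in]
        hi = np.minimum(lo + (ts[1] - ts[0]), t_max)
        for _ in range(48):  # bisection to ~1e-13 mm
            mid = 0.5 * (lo + hi)
            s = self.signed(pts_at(mid))
            take = s <= 0
            lo = np.where(take, mid, lo)
            hi = np.where(take, hi, mid)
        t = 0.5 * (lo + hi)
        return np.column_stack([cy + t * dirs[:, 0] / sy,
                                cx + t * dirs[:, 1] / sx])


def analytic_mask(params: PhantomParams) -> np.ndarray:
    """Voxel v is 1 iff its physical centre satisfies the analytic predicate."""
    shape = _BumpyEllipsoid(params)
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in params.grid_shape], indexing="ij")
    pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()]).astype(float)
    pts *= np.array(params.spacing)
    return (shape.signed(pts) <= 0).reshape(params.grid_shape)


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Volume + ground-truth mask + per-reader contours, all from one seed.

    The ground truth is the rasterization of the noiseless contours (shared
    ray-casting inside test); reader contours add per-vertex radial jitter.
    With zero jitter every reader's contour equals the noiseless one, so
    rasterizing any reader reproduces the ground truth exactly.
    """
    shape = _BumpyEllipsoid(params)
    nz, ny, nx = params.grid_shape
    gt = np.zeros(params.grid_shape, dtype=bool)
    clean_polys: dict[int, np.ndarray] = {}
    for z in range(nz):
        poly = shape.slice_polygon(z)
        if poly is None:
            continue
        clean_polys[z] = poly
        gt[z] = rasterize_polygon(poly, (ny, nx))

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xA1]))
    annotations: list[SliceAnnotation] = []
    sy, sx = params.spacing[1], params.spacing[2]
    cy, cx = params.nodule_center[1], params.nodule_center[2]
    for reader in range(params.n_readers):
        for z, poly in clean_polys.items():
            verts = poly
            if params.reader_jitter > 0:
                rel = (verts - [cy, cx]) * [sy, sx]  # mm offsets from centre
                t = np.linalg.norm(rel, axis=1)
                u = rel / np.where(t > 0, t, 1.0)[:, None]
                t_j = t + rng.normal(0.0, params.reader_jitter, len(t))
                t_j = np.maximum(t_j, 0.05 * t)  # keep the polygon star-shaped
                verts = np.column_stack([cy + t_j * u[:, 0] / sy,
                                         cx + t_j * u[:, 1] / sx])
            annotations.append(SliceAnnotation(reader, z, verts))

    noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xB2]))
    vol = np.full(params.grid_shape, params.background_intensity, dtype=float)
    vol[gt] = params.nodule_intensity
    if params.noise_sigma > 0:
        vol += noise_rng.normal(0.0, params.noise_sigma, params.grid_shape)
    return PhantomCase(VolumeImage(vol, params.spacing), gt, annotations, params)


# --- persistence ---------------------------------------------------------

def save_phantom(case: PhantomCase, out_dir) -> None:
    """Volume + GT as NIfTI, annotations and a manifest as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(case.volume, out_dir / "volume.nii.gz")
    save_volume(VolumeImage(case.gt_mask.astype(np.uint8), case.volume.spacing),
                out_dir / "gt_mask.nii.gz")
    ann = [{"reader_id": a.reader_id, "slice_index": a.slice_index,
            "vertices": a.vertices.tolist()} for a in case.annotations]
    (out_dir / "annotations.json").write_text(json.dumps(ann))
    manifest = {
        "files": ["volume.nii.gz", "gt_mask.nii.gz", "annotations.json"],
        "params": asdict(case.params),
        "seed": case.params.seed,
        "axis_order": "zyx",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_annotations(path) -> list[SliceAnnotation]:
    raw = json.loads(Path(path).read_text())
    return [SliceAnnotation(a["reader_id"], a["slice_index"],
                            np.asarray(a["vertices"])) for a in raw]
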