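"""Synthetic diffusion-weighted phantoms of a thin curved white-matter tract.

The phantom emulates a clinical whole-brain DTI acquisition of the optic
tracts: one set of b=0 volumes plus 32 diffusion directions at b=800 s/mm^2
on a 2.2 mm isotropic grid.  Two mirrored tubes (left/right tract analogs)
run mainly along the anterior-posterior axis; anterior of a designated
"chiasm" boundary the tubes converge toward the midline and overlap, so that
crossing-fiber mixing depresses FA there, and the apparent structure widens.
Voxels on the tube border mix tube and background tensors by sub-voxel
occupancy (partial volume).  Ground truth (centerline, noiseless FA,
chiasm slice) is reported in the resampled 1 mm space used by the analysis.

Coordinate convention (fixed throughout the package): 0-based voxel indices,
axis 0 = right-left, axis 1 = anterior-posterior (index 0 anterior-most),
axis 2 = inferior-superior.  A "coronal slice" is a fixed index on axis 1.
Voxel centers sit at ``index * voxel_size_mm`` in a shared mm frame, for the
acquisition grid and the 1 mm analysis grid alike.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

AXIS_RL, AXIS_AP, AXIS_IS = 0, 1, 2

#: signal level of the tube core / background on the b=0 image (arbitrary units)
S0_TUBE = 1000.0
S0_BACKGROUND = 500.0


def rng_from_keys(*keys) -> np.random.Generator:
    """Deterministic generator from a tuple of integers/strings.

    Strings are folded to integers so that seeds stay below 2**31 components;
    the same key tuple always yields the same stream.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(sum((i + 1) * b for i, b in enumerate(k.encode())) % (2**31))
        else:
            ints.append(int(k) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(ints))


def gradient_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (Fibonacci scheme)."""
    i = np.arange(n) + 0.5
    z = i / n  # (0, 1): upper hemisphere
    theta = np.pi * (1 + 5**0.5) * i
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def axially_symmetric_eigenvalues(fa: float, md: float) -> tuple[float, float]:
    """(lambda1, lambda23) of a prolate tensor with the given FA and MD."""
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1.0 + 2.0 * a), md * (1.0 - a)


def default_control_points() -> list[tuple[float, float, float]]:
    """Right-tract centerline control points (mm) for the default grid.

    The first point marks the posterior boundary of the chiasm analog; the
    curve bends gently in-plane, as the optic tract does around the midbrain.
    """
    xm = _default_x_mid()
    return [
        (xm - 7.0, 12.0, 13.0),
        (xm - 9.0, 28.0, 11.5),
        (xm - 11.0, 46.0, 14.0),
        (xm - 12.0, 64.0, 12.5),
    ]


def _default_x_mid() -> float:
    shape, voxel = (24, 32, 12), 2.2
    return (shape[0] - 1) * voxel / 2.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject's acquisition.

    ``centerline_control_points`` define the right tract in mm; the left
    tract is its mirror image about the mid-sagittal plane.  ``snr_b0`` is
    defined on the noiseless b=0 signal of the tube core.
    """

    grid_shape: tuple[int, int, int] = (24, 32, 12)
    voxel_size_mm: float = 2.2
    tract_radius_mm: float = 1.25
    centerline_control_points: list = field(default_factory=default_control_points)
    fa_core: float = 0.75
    md_core: float = 0.8e-3  # mm^2/s
    md_background: float = 1.0e-3  # mm^2/s
    b_value: float = 800.0  # s/mm^2
    n_directions: int = 32
    n_b0: int = 6
    snr_b0: float = 20.0
    noise_model: str = "rician"  # {rician, gaussian, none}
    t1w_offset_mm: float = 1.0
    seed: int = 0
    # shape refinements of the tube
    chiasm_extent_mm: float = 6.0  # anterior convergence zone length
    radius_taper: float = 0.4  # relative radius loss at the posterior end
    # repositioning amplitudes used by repeat_scan
    reposition_translation_sd_mm: float = 0.5
    reposition_rotation_sd_deg: float = 1.0

    def validate(self) -> None:
        if not (0.0 < self.fa_core < 1.0):
            raise ValueError(f"fa_core must be in (0, 1), got {self.fa_core}")
        if self.tract_radius_mm <= 0:
            raise ValueError("tract_radius_mm must be positive")
        if self.n_directions < 6:
            raise ValueError("at least 6 diffusion directions are required")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        pts = np.asarray(self.centerline_control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("centerline_control_points must be >= 2 points in mm")
        if np.any(np.diff(pts[:, AXIS_AP]) <= 0):
            raise ValueError("control points must advance along the AP axis")
        extent = pts[-1, AXIS_AP] - pts[0, AXIS_AP]
        if extent < 16.0:
            raise ValueError(
                "grid too small for the analysis: the tract spans "
                f"{extent:.1f} mm posterior of the chiasm but at least 16 mm "
                "(>= 15 coronal slices at 1 mm plus the start slice) are needed"
            )
        mm_extent = np.array(self.grid_shape) * self.voxel_size_mm
        lo = pts.min(axis=0) - self.tract_radius_mm
        hi = pts.max(axis=0) + self.tract_radius_mm
        if np.any(lo < 0) or np.any(hi > mm_extent):
            raise ValueError(
                "grid too small for the tract: centerline plus radius leaves "
                f"the field of view (extent {mm_extent} mm)"
            )

    @property
    def x_mid_mm(self) -> float:
        """Mid-sagittal plane position (mm)."""
        return (self.grid_shape[0] - 1) * self.voxel_size_mm / 2.0

    def grid_shape_at(self, target_mm: float) -> tuple[int, int, int]:
        return tuple(
            int(round(n * self.voxel_size_mm / target_mm)) for n in self.grid_shape
        )


@dataclass
class DWIDataset:
    """Diffusion volumes with their gradient table and voxel geometry.

    ``volumes`` is (x, y, z, volume); ``bvecs`` rows are unit vectors for
    b > 0 volumes and zero for b = 0 volumes.  Axis 1 is anterior-posterior
    with index 0 anterior-most.
    """

    volumes: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size_mm: float

    def validate(self) -> None:
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4-D (x, y, z, volume)")
        n = self.volumes.shape[3]
        if len(self.bvals) != n or len(self.bvecs) != n:
            raise ValueError("gradient table length does not match volume count")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            bad = int(np.flatnonzero(weighted)[np.argmax(np.abs(norms - 1.0))])
            raise ValueError(f"bvec row {bad} is not unit-norm for b>0")
        if np.any(self.volumes < 0):
            raise ValueError("signals must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[3]


@dataclass
class GroundTruth:
    """Known truth of one phantom in the 1 mm analysis space.

    ``centerline_voxels`` maps side -> ordered (x, y, z) voxel coordinates,
    one per coronal slice strictly posterior of ``chiasm_slice``.
    ``occupancy_map`` is the combined tube volume fraction per 1 mm voxel.
    """

    centerline_voxels: dict
    true_fa_map: np.ndarray
    chiasm_slice: int
    occupancy_map: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 1.0
    _geometry: "TractGeometry" = dataclasses.field(default=None, repr=False)

    def side_mask(self, side: str) -> np.ndarray:
        """Boolean mask of the hemifield holding the given tract."""
        return hemifield_mask(self.grid_shape, side)


def hemifield_mask(grid_shape, side: str) -> np.ndarray:
    """Right hemifield = lower axis-0 indices (axis 0 runs right to left)."""
    x_mid = (grid_shape[0] - 1) / 2.0
    x = np.arange(grid_shape[0], dtype=float)
    if side == "right":
        col = x < x_mid
    elif side == "left":
        col = x >= x_mid
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return np.broadcast_to(col[:, None, None], grid_shape).copy()


class TractGeometry:
    """Continuous model of the two mirrored tubes, queryable at mm points.

    An optional rigid transform (R, t about the grid center) models
    repositioning between repeat scans: fields are evaluated at the
    back-transformed points and tangents rotated forward.
    """

    def __init__(self, spec: PhantomSpec, rotation=None, translation=None):
        self.spec = spec
        pts = np.asarray(spec.centerline_control_points, dtype=float)
        self.y0 = float(pts[0, AXIS_AP])  # posterior chiasm boundary (mm)
        self.y1 = float(pts[-1, AXIS_AP])
        self.x_mid = spec.x_mid_mm
        # extend the curve anteriorly so both tubes converge near the midline
        ant = np.array(
            [[self.x_mid - 0.8, self.y0 - spec.chiasm_extent_mm, pts[0, AXIS_IS]]]
        )
        full = np.vstack([ant, pts])
        self.y_min = float(full[0, AXIS_AP])
        self._sx = CubicSpline(full[:, AXIS_AP], full[:, AXIS_RL])
        self._sz = CubicSpline(full[:, AXIS_AP], full[:, AXIS_IS])
        self.rotation = np.eye(3) if rotation is None else np.asarray(rotation)
        self.translation = (
            np.zeros(3) if translation is None else np.asarray(translation, float)
        )
        mm_extent = np.array(spec.grid_shape) * spec.voxel_size_mm
        self._center = mm_extent / 2.0

    # -- rigid transform ---------------------------------------------------
    def to_scanner(self, pts: np.ndarray) -> np.ndarray:
        """Apply the repositioning transform to object-frame points."""
        return (pts - self._center) @ self.rotation.T + self._center + self.translation

    def from_scanner(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self._center - self.translation) @ self.rotation + self._center

    # -- curve -------------------------------------------------------------
    def centerline_mm(self, y: np.ndarray, side: str) -> np.ndarray:
        """Object-frame centerline points at AP positions y (mm)."""
        y = np.asarray(y, dtype=float)
        x = self._sx(y)
        if side == "right":
            pass
        elif side == "left":
            x = 2.0 * self.x_mid - x
        else:
            raise ValueError(side)
        return np.stack([x, y, self._sz(y)], axis=-1)

    def tangent(self, y: np.ndarray, side: str) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        dx = self._sx(y, 1)
        if side == "left":
            dx = -dx
        t = np.stack([dx, np.ones_like(y), self._sz(y, 1)], axis=-1)
        t = t / np.linalg.norm(t, axis=-1, keepdims=True)
        return t @ self.rotation.T

    def radius_at(self, y: np.ndarray) -> np.ndarray:
        """Effective tube radius: posterior taper, anterior chiasm widening."""
        spec = self.spec
        y = np.asarray(y, dtype=float)
        frac = np.clip((y - self.y0) / (self.y1 - self.y0), 0.0, 1.0)
        # taper only past mid-tract: the analysis window is the anterior part
        taper_frac = np.clip((frac - 0.5) / 0.5, 0.0, 1.0)
        r = spec.tract_radius_mm * (1.0 - spec.radius_taper * taper_frac)
        widen = np.clip((self.y0 - y) / max(spec.chiasm_extent_mm, 1e-9), 0.0, 1.0)
        return r * (1.0 + 0.6 * widen)

    def inside(self, pts_scanner: np.ndarray, side: str) -> np.ndarray:
        """Boolean: scanner-frame points inside the tube of the given side."""
        p = self.from_scanner(np.asarray(pts_scanner, dtype=float))
        y = p[..., AXIS_AP]
        c = self.centerline_mm(y, side)
        r = np.hypot(p[..., AXIS_RL] - c[..., AXIS_RL], p[..., AXIS_IS] - c[..., AXIS_IS])
        return (r < self.radius_at(y)) & (y >= self.y_min) & (y <= self.y1)

    # -- voxel-level fields --------------------------------------------------
    def occupancy_fractions(self, grid_shape, voxel_mm: float, n_sub: int = 5):
        """Per-voxel volume fractions (f_right, f_left) by sub-voxel sampling.

        A sub-sample inside both tubes (the chiasm overlap) contributes half
        to each side, which is what mixes the two fiber populations there.
        """
        offsets = (np.arange(n_sub) + 0.5) / n_sub - 0.5
        idx = [np.arange(n, dtype=float) for n in grid_shape]
        gx, gy, gz = np.meshgrid(*idx, indexing="ij")
        base = np.stack([gx, gy, gz], axis=-1) * voxel_mm
        fr = np.zeros(grid_shape)
        fl = np.zeros(grid_shape)
        for ox in offsets:
            for oy in offsets:
                for oz in offsets:
                    pts = base + np.array([ox, oy, oz]) * voxel_mm
                    in_r = self.inside(pts, "right")
                    in_l = self.inside(pts, "left")
                    both = in_r & in_l
                    fr += in_r & ~both
                    fl += in_l & ~both
                    fr += 0.5 * both
                    fl += 0.5 * both
        n_tot = n_sub**3
        return fr / n_tot, fl / n_tot

    def tensor_field(self, grid_shape, voxel_mm: float, n_sub: int = 5):
        """Per-voxel ground-truth tensor (..., 3, 3) and combined occupancy."""
        spec = self.spec
        fr, fl = self.occupancy_fractions(grid_shape, voxel_mm, n_sub)
        lam1, lam23 = axially_symmetric_eigenvalues(spec.fa_core, spec.md_core)
        y_centers = np.arange(grid_shape[AXIS_AP], dtype=float) * voxel_mm
        d_bg = spec.md_background * np.eye(3)
        tensors = np.empty(grid_shape + (3, 3))
        tensors[:] = d_bg
        f_tot = fr + fl
        occupied = f_tot > 0
        if np.any(occupied):
            ix, iy, iz = np.nonzero(occupied)
            y_obj = self.from_scanner(
                np.stack([ix, iy, iz], axis=-1) * voxel_mm
            )[:, AXIS_AP]
            y_obj = np.clip(y_obj, self.y_min, self.y1)
            d_vox = np.zeros((len(ix), 3, 3))
            for side, f in (("right", fr), ("left", fl)):
                t = self.tangent(y_obj, side)
                d_side = lam23 * np.eye(3) + (lam1 - lam23) * np.einsum(
                    "ni,nj->nij", t, t
                )
                d_vox += f[ix, iy, iz, None, None] * d_side
            d_vox += (1.0 - f_tot[ix, iy, iz])[:, None, None] * d_bg
            tensors[ix, iy, iz] = d_vox
        # unused y_centers kept out; occupancy is returned for masks
        del y_centers
        return tensors, f_tot

    def centerline_voxels(self, grid_shape, voxel_mm: float) -> dict:
        """Per-side ordered centerline voxel per coronal slice (scanner frame)."""
        ny = grid_shape[AXIS_AP]
        out = {}
        for side in ("right", "left"):
            dense_y = np.linspace(self.y0, self.y1, 4 * int(self.y1 - self.y0) + 1)
            pts = self.to_scanner(self.centerline_mm(dense_y, side))
            entries = []
            for j in range(ny):
                y_mm = j * voxel_mm
                k = np.argmin(np.abs(pts[:, AXIS_AP] - y_mm))
                if abs(pts[k, AXIS_AP] - y_mm) > voxel_mm / 2.0:
                    continue
                vox = tuple(int(round(c / voxel_mm)) for c in pts[k])
                vox = (vox[0], j, vox[2])
                if all(0 <= vox[a] < grid_shape[a] for a in range(3)):
                    entries.append(vox)
            out[side] = entries
        return out

    def chiasm_slice(self, voxel_mm: float) -> int:
        """Most posterior coronal slice of the chiasm analog (scanner frame)."""
        boundary = self.to_scanner(self.centerline_mm(np.array([self.y0]), "right"))
        return int(np.floor(boundary[0, AXIS_AP] / voxel_mm + 0.5)) - 1


def _apply_noise(signals, noise_model, sigma, rng):
    if noise_model == "none" or sigma <= 0:
        return signals
    if noise_model == "gaussian":
        return np.clip(signals + rng.normal(0.0, sigma, signals.shape), 0.0, None)
    if noise_model == "rician":
        re = signals + rng.normal(0.0, sigma, signals.shape)
        im = rng.normal(0.0, sigma, signals.shape)
        return np.hypot(re, im)
    raise ValueError(noise_model)


def _synthesize(spec: PhantomSpec, geometry: TractGeometry, rng) -> DWIDataset:
    spec.validate()
    dirs = gradient_directions(spec.n_directions)
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), dirs])
    tensors, f_tot = geometry.tensor_field(
        spec.grid_shape, spec.voxel_size_mm, n_sub=5
    )
    s0 = S0_BACKGROUND + (S0_TUBE - S0_BACKGROUND) * np.clip(f_tot, 0.0, 1.0)
    n_vol = spec.n_b0 + spec.n_directions
    volumes = np.empty(spec.grid_shape + (n_vol,))
    for i in range(n_vol):
        if bvals[i] == 0:
            volumes[..., i] = s0
        else:
            g = bvecs[i]
            q = np.einsum("i,...ij,j->...", g, tensors, g)
            volumes[..., i] = s0 * np.exp(-bvals[i] * q)
    sigma = S0_TUBE / spec.snr_b0
    volumes = _apply_noise(volumes, spec.noise_model, sigma, rng)
    ds = DWIDataset(volumes=volumes, bvals=bvals, bvecs=bvecs,
                    voxel_size_mm=spec.voxel_size_mm)
    ds.validate()
    return ds


def _ground_truth(spec: PhantomSpec, geometry: TractGeometry) -> GroundTruth:
    from tractroi.dwi_model import fa_from_eigenvalues  # local to avoid cycle

    shape_1mm = spec.grid_shape_at(1.0)
    tensors, f_tot = geometry.tensor_field(shape_1mm, 1.0, n_sub=3)
    fa = np.zeros(shape_1mm)
    occupied = f_tot > 0
    if np.any(occupied):
        evals = np.linalg.eigvalsh(tensors[occupied])
        fa[occupied] = fa_from_eigenvalues(
            evals[:, 2], evals[:, 1], evals[:, 0]
        )
    chiasm = geometry.chiasm_slice(1.0)
    centerline = geometry.centerline_voxels(shape_1mm, 1.0)
    for side in centerline:
        centerline[side] = [v for v in centerline[side] if v[AXIS_AP] > chiasm]
    return GroundTruth(
        centerline_voxels=centerline,
        true_fa_map=fa,
        chiasm_slice=chiasm,
        occupancy_map=f_tot,
        grid_shape=shape_1mm,
        voxel_size_mm=1.0,
        _geometry=geometry,
    )


def generate_phantom(spec: PhantomSpec) -> tuple[DWIDataset, GroundTruth]:
    """Generate one synthetic acquisition plus its ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    geometry = TractGeometry(spec)
    rng = rng_from_keys(spec.seed, "noise", 0)
    data = _synthesize(spec, geometry, rng)
    truth = _ground_truth(spec, geometry)
    return data, truth


def _small_rotation(rng, sd_deg: float) -> np.ndarray:
    """Rotation by small random angles about the IS and RL axes."""
    az, ax = np.deg2rad(rng.normal(0.0, sd_deg, 2))
    cz, sz = np.cos(az), np.sin(az)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ rx


def repeat_scan(spec: PhantomSpec, scan_index: int) -> tuple[DWIDataset, GroundTruth]:
    """Re-acquire the same subject after repositioning in the scanner.

    A small random rigid transform (translation sd
    ``reposition_translation_sd_mm``, rotation sd
    ``reposition_rotation_sd_deg``) is applied to the whole object and fresh
    noise is drawn; both are seeded by (spec.seed, scan_index), so the same
    index always reproduces the same scan.  Ground truth is transformed
    consistently.
    """
    if scan_index < 0:
        raise ValueError("scan_index must be >= 0")
    spec.validate()
    rng_pose = rng_from_keys(spec.seed, "reposition", scan_index)
    rotation = _small_rotation(rng_pose, spec.reposition_rotation_sd_deg)
    translation = rng_pose.normal(0.0, spec.reposition_translation_sd_mm, 3)
    geometry = TractGeometry(spec, rotation=rotation, translation=translation)
    rng_noise = rng_from_keys(spec.seed, "noise", 1 + scan_index)
    data = _synthesize(spec, geometry, rng_noise)
    truth = _ground_truth(spec, geometry)
    return data, truth


@dataclass
class T1wContrast:
    """Anatomical-contrast volume on the 1 mm grid with its apparent centerline.

    The apparent tract is displaced from the truth by a smooth in-plane
    field of magnitude <= t1w_offset_mm, modelling residual misregistration
    of the anatomical image to diffusion space.
    """

    volume: np.ndarray
    apparent_centerline: dict
    offset_mm: float
    #: per-slice continuous displacement vectors (dx, dy, dz) in mm
    displacement_mm: dict = None


def make_t1w_contrast(truth: GroundTruth, spec: PhantomSpec) -> T1wContrast:
    """High-contrast tube image with a residual registration offset.

    The displacement is perpendicular to the AP axis (hence essentially
    perpendicular to the tract), constant in magnitude ``t1w_offset_mm`` and
    slowly rotating in direction along the tract; it is reproducible from
    ``spec.seed``.
    """
    if spec.t1w_offset_mm < 0:
        raise ValueError("t1w_offset_mm must be >= 0")
    geometry = truth._geometry
    shape = truth.grid_shape
    rng = rng_from_keys(spec.seed, "t1w")
    phi0 = rng.uniform(0.0, 2.0 * np.pi)

    def displacement(y_mm):
        phi = phi0 + np.pi * (np.asarray(y_mm) - geometry.y_min) / max(
            geometry.y1 - geometry.y_min, 1e-9
        )
        return spec.t1w_offset_mm * np.stack(
            [np.cos(phi), np.zeros_like(phi), np.sin(phi)], axis=-1
        )

    # occupancy of the displaced tube: sample points back-shifted by d(y)
    n_sub = 3
    offsets = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    idx = [np.arange(n, dtype=float) for n in shape]
    gx, gy, gz = np.meshgrid(*idx, indexing="ij")
    base = np.stack([gx, gy, gz], axis=-1)  # 1 mm grid: voxel == mm
    occ = np.zeros(shape)
    for ox in offsets:
        for oy in offsets:
            for oz in offsets:
                pts = base + np.array([ox, oy, oz])
                shifted = pts - displacement(pts[..., AXIS_AP])
                occ += geometry.inside(shifted, "right")
                occ += geometry.inside(shifted, "left")
    occ = np.clip(occ / n_sub**3, 0.0, 1.0)
    volume = 150.0 + 850.0 * occ

    apparent = {}
    disp = {}
    for side, entries in truth.centerline_voxels.items():
        moved = []
        for (x, y, z) in entries:
            d = displacement(float(y))
            disp[y] = tuple(float(c) for c in d)
            moved.append((int(round(x + d[0])), y, int(round(z + d[2]))))
        apparent[side] = moved
    return T1wContrast(volume=volume, apparent_centerline=apparent,
                       offset_mm=spec.t1w_offset_mm, displacement_mm=disp)
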