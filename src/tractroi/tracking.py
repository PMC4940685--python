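"""Desk-scale probabilistic tractography surrogate.

Streamlines are launched bidirectionally from each seed voxel and follow the
principal eigenvector of the trilinearly interpolated tensor field,
sign-aligned with the previous step and perturbed at every step by a random
angular deviation (the uncertainty surrogate for a sampled fiber-orientation
posterior).  A streamline stops on reaching the termination mask, leaving
the grid, FA dropping below ``fa_stop``, exceeding ``max_steps``, or turning
more than ``curvature_threshold_deg`` in one step.  Streamlines touching the
exclusion mask are discarded entirely; the remaining (accepted) streamlines
increment per-voxel visitation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tractroi.dwi_model import TensorField, six_to_matrix
from tractroi.phantom import rng_from_keys


@dataclass
class TrackingConfig:
    n_streamlines: int = 1000  # per seed voxel
    step_mm: float = 0.5
    angle_dispersion_deg: float = 10.0
    max_steps: int = 300
    curvature_threshold_deg: float = 45.0
    fa_stop: float = 0.1
    seed: int = 0

    def validate(self, voxel_mm: float) -> None:
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if not (0.0 < self.step_mm <= voxel_mm):
            raise ValueError("step_mm must be in (0, one voxel]")
        if self.fa_stop < 0:
            raise ValueError("fa_stop must be >= 0")


@dataclass
class VisitationMap:
    counts: np.ndarray  # int, per voxel
    n_launched: int
    n_accepted: int
    #: accepted streamlines that hit the termination mask in >= 1 direction
    n_reached: int = 0


def _interp_channels(fields: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of (..., C) fields at (N, 3) voxel positions."""
    out = np.empty((len(pts),) + fields.shape[3:])
    coords = pts.T
    if fields.ndim == 3:
        return ndimage.map_coordinates(fields, coords, order=1, mode="nearest")
    for c in range(fields.shape[3]):
        out[:, c] = ndimage.map_coordinates(
            fields[..., c], coords, order=1, mode="nearest"
        )
    return out


def _principal_dirs(tensor6: np.ndarray, pts: np.ndarray) -> np.ndarray:
    six = _interp_channels(tensor6, pts)
    mats = six_to_matrix(six)
    _, v = np.linalg.eigh(mats)
    return v[:, :, 2]  # eigenvector of the largest eigenvalue


def _perturb(dirs: np.ndarray, sd_rad: float, rng) -> np.ndarray:
    """Rotate each direction by an angle ~ N(0, sd) about a random normal axis."""
    if sd_rad <= 0:
        return dirs
    n = len(dirs)
    raw = rng.normal(size=(n, 3))
    axis = raw - (np.sum(raw * dirs, axis=1, keepdims=True)) * dirs
    norm = np.linalg.norm(axis, axis=1, keepdims=True)
    norm[norm < 1e-12] = 1.0
    axis /= norm
    ang = rng.normal(0.0, sd_rad, n)[:, None]
    cos, sin = np.cos(ang), np.sin(ang)
    cross = np.cross(axis, dirs)
    return cos * dirs + sin * cross  # Rodrigues with axis _|_ dirs


def track(
    tensors: TensorField,
    seed_mask: np.ndarray,
    termination_mask: np.ndarray,
    exclusion_mask: np.ndarray | None,
    cfg: TrackingConfig,
) -> VisitationMap:
    """Visitation-count map from seed/termination/exclusion masks.

    Reproducible for a fixed ``cfg.seed``.
    """
    cfg.validate(tensors.voxel_size_mm)
    shape = tensors.fa_map.shape
    seeds = np.argwhere(seed_mask)
    if len(seeds) == 0:
        raise ValueError("seed mask is empty")
    if exclusion_mask is None:
        exclusion_mask = np.zeros(shape, dtype=bool)
    if np.any(seed_mask & (termination_mask | exclusion_mask)):
        raise ValueError("termination/exclusion masks overlap the seed mask")
    if np.any(tensors.fa_map[tuple(seeds.T)] < cfg.fa_stop):
        raise ValueError("seed voxels must have FA >= fa_stop")

    rng = rng_from_keys(cfg.seed, "track")
    sd_rad = np.deg2rad(cfg.angle_dispersion_deg)
    cos_curv = np.cos(np.deg2rad(cfg.curvature_threshold_deg))
    step_vox = cfg.step_mm / tensors.voxel_size_mm
    upper = np.asarray(shape, dtype=float) - 1.0

    n = len(seeds) * cfg.n_streamlines
    start = np.repeat(seeds.astype(float), cfg.n_streamlines, axis=0)
    init_dir = _principal_dirs(tensors.tensor, start)

    excluded = np.zeros(n, dtype=bool)
    reached = np.zeros(n, dtype=bool)
    visited = [set() for _ in range(n)]
    seed_vox = np.round(start).astype(int)
    for i in range(n):
        visited[i].add(tuple(seed_vox[i]))

    for orientation in (1.0, -1.0):
        pos = start.copy()
        prev = orientation * init_dir.copy()
        active = np.ones(n, dtype=bool)
        for _ in range(cfg.max_steps):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            p = pos[idx]
            d = _principal_dirs(tensors.tensor, p)
            flip = np.sum(d * prev[idx], axis=1) < 0
            d[flip] = -d[flip]
            d = _perturb(d, sd_rad, rng)
            # curvature stop: angle between consecutive steps
            turn_ok = np.sum(d * prev[idx], axis=1) >= cos_curv
            new_p = p + step_vox * d
            in_grid = np.all((new_p >= 0) & (new_p <= upper), axis=1)
            ok = turn_ok & in_grid
            stopped = idx[~ok]
            active[stopped] = False
            moved = idx[ok]
            if len(moved) == 0:
                continue
            pos[moved] = new_p[ok]
            prev[moved] = d[ok]
            vox = np.round(new_p[ok]).astype(int)
            fa_here = _interp_channels(tensors.fa_map, new_p[ok])
            exc = exclusion_mask[tuple(vox.T)]
            term = termination_mask[tuple(vox.T)]
            for j, m in enumerate(moved):
                visited[m].add(tuple(vox[j]))
            excluded[moved[exc]] = True
            reached[moved[term & ~exc]] = True
            active[moved[exc | term]] = False
            active[moved[fa_here < cfg.fa_stop]] = False

    counts = np.zeros(shape, dtype=np.int64)
    n_accepted = 0
    for i in range(n):
        if excluded[i]:
            continue
        n_accepted += 1
        vox = np.array(sorted(visited[i]))
        counts[tuple(vox.T)] += 1
    return VisitationMap(counts=counts, n_launched=n, n_accepted=n_accepted,
                         n_reached=int((reached & ~excluded).sum()))
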