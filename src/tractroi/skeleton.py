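"""Individual-space FA skeletonization.

Marks voxels whose FA is a local maximum along the direction perpendicular
to the local tract, then removes marked voxels with FA below a threshold
(default 0.2, excluding voxels that are mostly gray matter or CSF).  The
perpendicular direction is the FA gradient of the Gaussian-smoothed map
where that gradient is substantial (off the ridge top it points at the tract
center, so off-axis voxels fail the maximum test against their up-gradient
neighbor); on the ridge top, where the gradient vanishes or the curvature is
ambiguous, the eigenvector of the most negative Hessian eigenvalue is used.

The comparison against the two interpolated samples one voxel away along the
perpendicular is strict on the positive side and non-strict on the negative
side (direction sign canonicalised), so a flat two-voxel ridge top keeps
exactly one voxel and a constant map yields an empty skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EPS = 1e-6
_DEGENERACY_RATIO = 1.1
_GRADIENT_FLOOR = 0.03  # FA per voxel: above this the gradient sets the direction


@dataclass
class SkeletonMask:
    """Skeleton voxels with the per-voxel perpendicular direction used."""

    voxels: np.ndarray  # bool, full grid
    perpendicular_direction: np.ndarray  # (..., 3), zero off-skeleton
    fa_threshold: float

    def coordinates(self) -> np.ndarray:
        return np.argwhere(self.voxels)


def _perpendicular_directions(fa_sm: np.ndarray, candidates: np.ndarray):
    """Perpendicular direction per candidate voxel (N, 3)."""
    grads = np.gradient(fa_sm)
    g = np.stack([grads[i][tuple(candidates.T)] for i in range(3)], axis=1)
    gnorm = np.linalg.norm(g, axis=1)

    h = np.empty((len(candidates), 3, 3))
    for i in range(3):
        gi = np.gradient(grads[i])
        for j in range(3):
            h[:, i, j] = gi[j][tuple(candidates.T)]
    h = 0.5 * (h + np.swapaxes(h, 1, 2))
    w, v = np.linalg.eigh(h)  # ascending: w[:,0] most negative
    perp = v[:, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(w[:, 0]) / np.maximum(np.abs(w[:, 1]), 1e-30)
    degenerate = ratio < _DEGENERACY_RATIO
    use_grad = (gnorm > _GRADIENT_FLOOR) | (degenerate & (gnorm > 1e-12))
    perp[use_grad] = g[use_grad] / gnorm[use_grad, None]
    return perp


def _canonical_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip vectors so the first component exceeding 1e-8 is positive."""
    out = vecs.copy()
    sign = np.zeros(len(vecs))
    for axis in range(3):
        undecided = sign == 0
        comp = out[undecided, axis]
        s = np.where(np.abs(comp) > 1e-8, np.sign(comp), 0.0)
        sign[undecided] = s
    sign[sign == 0] = 1.0
    return out * sign[:, None]


def local_maxima(fa_map: np.ndarray, sigma: float = 1.0, min_fa: float = 0.05):
    """Ridge voxels of the FA map before any FA threshold.

    Returns (bool mask, per-voxel perpendicular directions).
    """
    fa = np.asarray(fa_map, dtype=float)
    mask = np.zeros(fa.shape, dtype=bool)
    dirs = np.zeros(fa.shape + (3,))
    candidates = np.argwhere(fa > min_fa)
    if len(candidates) == 0:
        return mask, dirs
    fa_sm = ndimage.gaussian_filter(fa, sigma)
    perp = _canonical_sign(_perpendicular_directions(fa_sm, candidates))
    pts = candidates.astype(float)
    plus = ndimage.map_coordinates(fa, (pts + perp).T, order=1, mode="nearest")
    minus = ndimage.map_coordinates(fa, (pts - perp).T, order=1, mode="nearest")
    center = fa[tuple(candidates.T)]
    marked = (center - plus > _EPS) & (center - minus > -_EPS)
    sel = candidates[marked]
    mask[tuple(sel.T)] = True
    dirs[tuple(sel.T)] = perp[marked]
    return mask, dirs


def skeletonize_fa(fa_map: np.ndarray, fa_threshold: float = 0.2,
                   sigma: float = 1.0) -> SkeletonMask:
    """FA skeleton of one subject's map in its native space.

    An empty or constant map yields an empty skeleton (no ridge exists).
    """
    fa = np.asarray(fa_map, dtype=float)
    if fa.size and (fa.min() < -1e-9 or fa.max() > 1.0 + 1e-9):
        raise ValueError("fa_map values must lie in [0, 1]")
    mask, dirs = local_maxima(fa, sigma=sigma)
    keep = mask & (fa >= fa_threshold)
    dirs = np.where(keep[..., None], dirs, 0.0)
    return SkeletonMask(voxels=keep, perpendicular_direction=dirs,
                        fa_threshold=fa_threshold)
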