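"""Resampling to 1 mm isotropic, diffusion-tensor fitting, FA maps.

The tensor is fitted by ordinary log-linear least squares,
``ln S = ln S0 - b g' D g``, per voxel; FA comes from the eigenvalues of the
fitted tensor (negative eigenvalues clamped to zero and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from tractroi.phantom import DWIDataset


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from three eigenvalues (scalars or arrays).

    FA = sqrt(3/2) * sqrt(sum (li - mean)^2) / sqrt(sum li^2); 0 for perfect
    isotropy, -> 1 as two eigenvalues vanish.  All-zero input is defined as 0.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    mean = (l1 + l2 + l3) / 3.0
    num = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    fa = np.where(den > 0, fa, 0.0)
    out = np.clip(fa, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class TensorField:
    """Per-voxel fitted tensor with its eigen-decomposition and FA.

    ``tensor`` stores the six unique components (Dxx, Dyy, Dzz, Dxy, Dxz,
    Dyz) in mm^2/s; ``eigenvalues`` are sorted descending.
    """

    tensor: np.ndarray  # (..., 6)
    eigenvalues: np.ndarray  # (..., 3), descending
    principal_direction: np.ndarray  # (..., 3), unit
    fa_map: np.ndarray
    s0_map: np.ndarray
    negative_clamped: np.ndarray  # bool: any eigenvalue clamped at 0
    voxel_size_mm: float = 1.0

    def tensor_matrices(self) -> np.ndarray:
        """Full symmetric (..., 3, 3) tensors."""
        return six_to_matrix(self.tensor)


def six_to_matrix(six: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(six, -1, 0)
    m = np.empty(six.shape[:-1] + (3, 3))
    m[..., 0, 0] = dxx
    m[..., 1, 1] = dyy
    m[..., 2, 2] = dzz
    m[..., 0, 1] = m[..., 1, 0] = dxy
    m[..., 0, 2] = m[..., 2, 0] = dxz
    m[..., 1, 2] = m[..., 2, 1] = dyz
    return m


def resample_isotropic(data: DWIDataset, target_mm: float = 1.0) -> DWIDataset:
    """Interpolate all volumes onto an isotropic grid of edge ``target_mm``.

    Cubic B-spline interpolation (a sinc-like kernel); samples falling
    outside the source grid are set to 0.  Voxel centers of both grids share
    the mm frame with voxel 0 at 0 mm.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if target_mm > data.voxel_size_mm:
        raise ValueError("target_mm must not exceed the source voxel size")
    src = data.voxel_size_mm
    shape_out = tuple(int(round(n * src / target_mm)) for n in data.volumes.shape[:3])
    coords = np.meshgrid(
        *[np.arange(n, dtype=float) * target_mm / src for n in shape_out],
        indexing="ij",
    )
    coords = np.stack(coords)
    out = np.empty(shape_out + (data.n_volumes,))
    for i in range(data.n_volumes):
        out[..., i] = ndimage.map_coordinates(
            data.volumes[..., i], coords, order=3, mode="constant", cval=0.0
        )
    out = np.clip(out, 0.0, None)  # spline overshoot must not produce signals < 0
    return DWIDataset(
        volumes=out, bvals=data.bvals.copy(), bvecs=data.bvecs.copy(),
        voxel_size_mm=target_mm,
    )


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(data: DWIDataset, mask: np.ndarray | None = None) -> TensorField:
    """Ordinary log-linear least-squares tensor fit per voxel.

    Requires >= 7 volumes spanning >= 6 non-collinear directions.  Signals
    are clamped at a small positive floor before the log.  Negative
    eigenvalues are clamped to 0 (flagged) before FA.
    """
    x = design_matrix(data.bvals, data.bvecs)
    if x.shape[0] < 7:
        raise ValueError("tensor fit needs at least 7 volumes (b0 + 6 directions)")
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError(
            "gradient scheme is rank-deficient (collinear directions): the "
            "tensor is not identifiable"
        )
    shape = data.volumes.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    signals = data.volumes[mask]  # (N, n_vol)
    floor = max(1e-12, 1e-9 * float(signals.max(initial=0.0)))
    log_s = np.log(np.maximum(signals, floor))
    beta = log_s @ np.linalg.pinv(x).T  # (N, 7)

    tensor = np.zeros(shape + (6,))
    tensor[mask] = beta[:, 1:]
    s0_map = np.zeros(shape)
    s0_map[mask] = np.exp(beta[:, 0])

    evals_full = np.zeros(shape + (3,))
    evecs_full = np.zeros(shape + (3,))
    evecs_full[..., 0] = 1.0
    fa_map = np.zeros(shape)
    clamped = np.zeros(shape, dtype=bool)

    mats = six_to_matrix(beta[:, 1:])
    w, v = np.linalg.eigh(mats)  # ascending
    w_desc = w[:, ::-1]
    principal = v[:, :, 2]
    neg = w_desc[:, 2] < 0
    w_clamped = np.clip(w_desc, 0.0, None)
    evals_full[mask] = w_clamped
    evecs_full[mask] = principal
    fa_map[mask] = fa_from_eigenvalues(
        w_clamped[:, 0], w_clamped[:, 1], w_clamped[:, 2]
    )
    clamped[mask] = neg
    return TensorField(
        tensor=tensor,
        eigenvalues=evals_full,
        principal_direction=evecs_full,
        fa_map=fa_map,
        s0_map=s0_map,
        negative_clamped=clamped,
        voxel_size_mm=data.voxel_size_mm,
    )


def mean_b0(data: DWIDataset) -> np.ndarray:
    """Average of the b=0 volumes (the 'b0 map' used for manual tracing)."""
    sel = data.bvals == 0
    if not np.any(sel):
        raise ValueError("dataset has no b=0 volume")
    return data.volumes[..., sel].mean(axis=-1)
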