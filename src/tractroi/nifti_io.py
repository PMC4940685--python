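"""NIfTI / FSL-gradient-table / JSON / CSV input-output.

Volumes are written as NIfTI-1 (.nii.gz) with a diagonal affine carrying the
voxel size; gradient tables use the FSL convention (one row of b-values,
three rows of direction components); ROIs and ground truth use JSON
sidecars.  Readers validate what they load (unit-norm bvecs, mask dtypes)
and fail with the offending row or file named.
"""

from __future__ import annotations

import json
import os

import numpy as np
import nibabel as nib

from tractroi.phantom import DWIDataset, GroundTruth
from tractroi.roi_methods import Roi


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(path: str, data: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size_mm)), path)


def load_volume(path: str) -> tuple[np.ndarray, float]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(path)
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel


def save_mask(path: str, mask: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    save_volume(path, mask.astype(np.uint8), voxel_size_mm)


def load_mask(path: str) -> np.ndarray:
    data, _ = load_volume(path)
    return data.astype(bool)


def save_dwi(prefix: str, data: DWIDataset) -> None:
    """Write ``prefix.nii.gz`` plus FSL-style ``prefix.bval``/``prefix.bvec``."""
    save_volume(prefix + ".nii.gz", data.volumes, data.voxel_size_mm)
    np.savetxt(prefix + ".bval", data.bvals[None, :], fmt="%.1f")
    np.savetxt(prefix + ".bvec", data.bvecs.T, fmt="%.8f")


def load_dwi(prefix: str) -> DWIDataset:
    volumes, voxel = load_volume(prefix + ".nii.gz")
    bvals = np.atleast_1d(np.loadtxt(prefix + ".bval"))
    bvecs = np.loadtxt(prefix + ".bvec").T
    if bvecs.ndim == 1:
        bvecs = bvecs[None, :]
    for i, (b, g) in enumerate(zip(bvals, bvecs)):
        if b > 0 and abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise ValueError(f"bvec row {i} is not unit-norm (b={b:g})")
    ds = DWIDataset(volumes=volumes, bvals=bvals, bvecs=bvecs, voxel_size_mm=voxel)
    ds.validate()
    return ds


def save_roi(path: str, roi: Roi) -> None:
    payload = {
        "method": roi.method,
        "side": roi.side,
        "start_slice": roi.start_slice,
        "selections": [[list(map(int, v)) for v in sel] for sel in roi.selections],
        "rater_id": roi.rater_id,
        "scan_id": roi.scan_id,
        "repeat_id": roi.repeat_id,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_roi(path: str) -> Roi:
    if not os.path.exists(path):
        raise FileNotFoundError(f"ROI file not found: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    roi = Roi(
        method=payload["method"],
        side=payload["side"],
        start_slice=int(payload["start_slice"]),
        selections=[[tuple(v) for v in sel] for sel in payload["selections"]],
        rater_id=payload.get("rater_id", ""),
        scan_id=int(payload.get("scan_id", 0)),
        repeat_id=int(payload.get("repeat_id", 0)),
    )
    roi.validate()
    return roi


def save_ground_truth(prefix: str, truth: GroundTruth) -> None:
    """Binary occupancy/FA maps as NIfTI plus a JSON centerline sidecar."""
    save_volume(prefix + "_true_fa.nii.gz", truth.true_fa_map, truth.voxel_size_mm)
    save_mask(prefix + "_tube_mask.nii.gz", truth.occupancy_map > 0.25,
              truth.voxel_size_mm)
    sidecar = {
        "chiasm_slice": truth.chiasm_slice,
        "grid_shape": list(truth.grid_shape),
        "voxel_size_mm": truth.voxel_size_mm,
        "centerline_voxels": {
            side: [list(map(int, v)) for v in entries]
            for side, entries in truth.centerline_voxels.items()
        },
    }
    with open(prefix + "_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_ground_truth(prefix: str) -> GroundTruth:
    fa, voxel = load_volume(prefix + "_true_fa.nii.gz")
    occ = load_mask(prefix + "_tube_mask.nii.gz").astype(float)
    with open(prefix + "_truth.json") as fh:
        sidecar = json.load(fh)
    return GroundTruth(
        centerline_voxels={
            side: [tuple(v) for v in entries]
            for side, entries in sidecar["centerline_voxels"].items()
        },
        true_fa_map=fa,
        chiasm_slice=int(sidecar["chiasm_slice"]),
        occupancy_map=occ,
        grid_shape=tuple(sidecar["grid_shape"]),
        voxel_size_mm=float(sidecar["voxel_size_mm"]),
    )
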