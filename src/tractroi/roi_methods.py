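"""The four ROI-definition procedures with simulated raters.

Shared rules across methods: the anterior limit of every ROI is the coronal
slice of the most posterior chiasm, identified once per rater sitting and
reused for all four methods; at most two voxels are selected per coronal
slice (one when the cross-section is a single voxel); the 15 most anterior
slices enter the statistics, split into three 5 mm sections.

Human raters are replaced by parameterised stochastic models: a rater
perturbs the anterior-limit slice (rounded Gaussian jitter) and, for the
manual methods, the in-plane "most central" judgement (Gaussian jitter of
the cross-section centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from tractroi.phantom import AXIS_AP, GroundTruth, hemifield_mask, rng_from_keys
from tractroi.skeleton import SkeletonMask
from tractroi.tracking import VisitationMap

METHODS = ("manual_b0", "manual_t1w", "fa_skeleton", "tractography")


@dataclass
class RaterModel:
    """Stochastic stand-in for one human rater.

    ``start_slice_jitter_sd`` (slices) perturbs the anterior limit;
    ``inplane_jitter_sd`` (mm) perturbs the centroid used for "most central"
    voxel selection; ``selection_temperature`` > 0 softens the nearest-voxel
    choice into a probabilistic one (0 = deterministic).
    """

    rater_id: str
    start_slice_jitter_sd: float = 1.0
    inplane_jitter_sd: float = 0.5
    selection_temperature: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.start_slice_jitter_sd < 0 or self.inplane_jitter_sd < 0:
            raise ValueError("jitter standard deviations must be >= 0")

    def rng(self, *keys) -> np.random.Generator:
        return rng_from_keys(self.seed, self.rater_id, *keys)


@dataclass
class Roi:
    """Ordered per-coronal-slice voxel selections of one tract.

    ``selections[i]`` lists the voxels chosen in slice ``start_slice + i``
    (1-2 voxels; an empty list records a gap, which only the skeleton method
    can produce).  Slices run anterior to posterior.
    """

    method: str
    side: str
    start_slice: int
    selections: list = field(default_factory=list)
    rater_id: str = ""
    scan_id: int = 0
    repeat_id: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        for i, sel in enumerate(self.selections):
            if len(sel) > 2:
                raise ValueError(
                    f"slice {self.start_slice + i}: {len(sel)} voxels selected, "
                    "the maximum is two per coronal slice"
                )
            for v in sel:
                if v[AXIS_AP] != self.start_slice + i:
                    raise ValueError("selection voxel lies outside its slice")

    @property
    def n_slices(self) -> int:
        return len(self.selections)

    @property
    def slices(self) -> list[int]:
        return [self.start_slice + i for i in range(self.n_slices)]

    def voxel_set(self, slice_range: tuple[int, int] | None = None) -> set:
        """All selected voxels, optionally restricted to [lo, hi] slices."""
        out = set()
        for i, sel in enumerate(self.selections):
            s = self.start_slice + i
            if slice_range is not None and not (slice_range[0] <= s <= slice_range[1]):
                continue
            out.update(tuple(v) for v in sel)
        return out

    @property
    def gap_slices(self) -> list[int]:
        return [self.start_slice + i for i, s in enumerate(self.selections) if not s]


def find_anterior_limit(
    truth: GroundTruth,
    rater: RaterModel,
    subject_key: int = 0,
    repeat_key: int = 0,
) -> int:
    """Anterior ROI limit: the chiasm slice perturbed by the rater.

    Rounded Gaussian jitter of sd ``start_slice_jitter_sd``, clamped so at
    least 15 slices remain posterior; deterministic per
    (rater, subject, repeat).  One sitting reuses this slice for all methods.
    """
    rng = rater.rng("start", subject_key, repeat_key)
    jitter = int(np.round(rng.normal(0.0, rater.start_slice_jitter_sd)))
    ny = truth.grid_shape[AXIS_AP]
    return int(np.clip(truth.chiasm_slice + jitter, 0, ny - 16))


def _segment_cross_section(plane: np.ndarray, hemi: np.ndarray):
    """Tract cross-section on one coronal plane of a contrast image.

    Thresholds at 40 % of the local peak-over-background contrast within the
    hemifield, keeps the largest connected component, and returns
    (voxel coords (N, 2), contrast-to-noise ratio).  Noise is estimated
    robustly from sub-threshold voxels (1.4826 * MAD); a noiseless image
    yields CNR = inf.
    """
    vals = plane[hemi]
    bg = float(np.median(vals))
    peak = float(vals.max())
    if peak <= bg:
        return np.empty((0, 2), dtype=int), 0.0
    thr = bg + 0.4 * (peak - bg)
    above = (plane > thr) & hemi
    if not above.any():
        return np.empty((0, 2), dtype=int), 0.0
    labels, n = ndimage.label(above)
    if n > 1:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        above = labels == (1 + int(np.argmax(sizes)))
    below = vals[vals <= thr]
    mad = float(np.median(np.abs(below - np.median(below)))) if below.size else 0.0
    noise_sd = 1.4826 * mad
    signal = float(plane[above].mean()) - bg
    cnr = np.inf if noise_sd <= 0 else signal / noise_sd
    return np.argwhere(above), cnr


def _nearest_voxels(coords: np.ndarray, target: np.ndarray, k: int = 2,
                    temperature: float = 0.0, rng=None) -> np.ndarray:
    """The k cross-section voxels nearest the (possibly jittered) centroid."""
    d = np.linalg.norm(coords - target, axis=1)
    order = np.lexsort((coords[:, 1], coords[:, 0], d))
    if temperature > 0 and rng is not None and len(coords) > k:
        w = np.exp(-d / temperature)
        w /= w.sum()
        pick = rng.choice(len(coords), size=min(k, len(coords)), replace=False, p=w)
        return coords[np.sort(pick)]
    return coords[order[:k]]


def roi_manual(
    image: np.ndarray,
    fa_map: np.ndarray,
    start_slice: int,
    rater: RaterModel,
    side: str,
    method: str = "manual_b0",
    subject_key: int = 0,
    repeat_key: int = 0,
    max_slices: int = 40,
) -> Roi:
    """Manual tracing on a contrast image (the b0 map or the T1W-like volume).

    Per coronal slice from ``start_slice``: segment the tract cross-section,
    jitter its centroid in-plane by the rater's sd, and select the two
    cross-section voxels nearest the jittered centroid (one if the section is
    a single voxel).  Selection proceeds posteriorly until the cross-section
    is no longer separable from background: empty, or contrast-to-noise
    ratio < 1 on two consecutive slices.
    """
    if image.shape != fa_map.shape:
        raise ValueError("contrast image and FA map must share the 1 mm grid")
    hemi3d = hemifield_mask(image.shape, side)
    rng = rater.rng("inplane", method, subject_key, repeat_key, side)
    selections = []
    low_cnr_run = 0
    ny = image.shape[AXIS_AP]
    for y in range(start_slice, min(start_slice + max_slices, ny)):
        coords2d, cnr = _segment_cross_section(image[:, y, :], hemi3d[:, y, :])
        if len(coords2d) == 0:
            if not selections:
                raise ValueError(
                    f"empty tract cross-section at the start slice {y}: the "
                    "anterior limit does not match the phantom"
                )
            break
        if cnr < 1.0:
            low_cnr_run += 1
            if low_cnr_run >= 2:
                break
        else:
            low_cnr_run = 0
        centroid = coords2d.mean(axis=0)
        jitter = rng.normal(0.0, rater.inplane_jitter_sd, 2)
        chosen = _nearest_voxels(coords2d, centroid + jitter, k=2,
                                 temperature=rater.selection_temperature, rng=rng)
        selections.append([(int(x), y, int(z)) for x, z in chosen])
    roi = Roi(method=method, side=side, start_slice=start_slice,
              selections=selections, rater_id=rater.rater_id)
    roi.validate()
    return roi


def roi_from_skeleton(
    skeleton: SkeletonMask,
    fa_map: np.ndarray,
    start_slice: int,
    tract_neighborhood_mask: np.ndarray,
    rater: RaterModel,
    side: str,
) -> Roi:
    """ROI guided by the FA skeleton.

    Per slice the candidates are skeleton voxels inside the tract
    neighborhood (the rater's identification of which skeleton branch is the
    tract); with more than two candidates the two with highest FA nearest
    the tract middle are kept, ties broken by distance to the candidate
    centroid, then lexicographically.  Slices with no candidate contribute
    nothing (recorded as gaps).  The rater influences only the start slice
    and the neighborhood.
    """
    hemi = hemifield_mask(fa_map.shape, side)
    candidates3d = skeleton.voxels & tract_neighborhood_mask & hemi
    ny = fa_map.shape[AXIS_AP]
    neigh = tract_neighborhood_mask & hemi
    last = start_slice
    for y in range(start_slice, ny):
        if neigh[:, y, :].any():
            last = y
        else:
            break
    selections = []
    for y in range(start_slice, last + 1):
        coords = np.argwhere(candidates3d[:, y, :])
        if len(coords) == 0:
            selections.append([])
            continue
        fa_vals = fa_map[coords[:, 0], y, coords[:, 1]]
        middle = coords.astype(float).mean(axis=0)
        dist = np.linalg.norm(coords - middle, axis=1)
        order = np.lexsort((coords[:, 1], coords[:, 0], dist, -fa_vals))
        chosen = coords[order[:2]]
        selections.append([(int(x), y, int(z)) for x, z in chosen])
    while selections and not selections[-1]:
        selections.pop()
    if not any(selections):
        raise ValueError(
            "the FA skeleton does not intersect the tract neighborhood in any "
            "slice at or after the start slice"
        )
    roi = Roi(method="fa_skeleton", side=side, start_slice=start_slice,
              selections=selections, rater_id=rater.rater_id)
    roi.validate()
    return roi


def roi_from_tracking(
    visitation: VisitationMap,
    fa_map: np.ndarray,
    start_slice: int,
    side: str,
) -> Roi:
    """ROI from a tractography visitation map.

    Per slice the candidates are voxels with counts > 0; the two with the
    highest FA are selected (ties broken by higher count, then lexicographic
    voxel order).  The ROI begins at the first slice at or after
    ``start_slice`` that the tractography visits (when the streamlines did
    not extend all the way to the anterior limit, the ROI starts where the
    tract map starts) and stops at the next slice without candidates.  A
    visitation map empty at and after ``start_slice`` is rejected.
    """
    hemi = hemifield_mask(fa_map.shape, side)
    pos = (visitation.counts > 0) & hemi
    ny = fa_map.shape[AXIS_AP]
    selections = []
    roi_start = start_slice
    for y in range(start_slice, ny):
        coords = np.argwhere(pos[:, y, :])
        if len(coords) == 0:
            if not selections:
                continue  # tractography has not started yet
            break
        if not selections:
            roi_start = y
        fa_vals = fa_map[coords[:, 0], y, coords[:, 1]]
        cnt = visitation.counts[coords[:, 0], y, coords[:, 1]]
        order = np.lexsort((coords[:, 1], coords[:, 0], -cnt, -fa_vals))
        chosen = coords[order[:2]]
        selections.append([(int(x), y, int(z)) for x, z in chosen])
    if not selections:
        raise ValueError(
            "no tractography-visited voxels at or after the start slice "
            f"{start_slice}"
        )
    roi = Roi(method="tractography", side=side, start_slice=roi_start,
              selections=selections)
    roi.validate()
    return roi


@dataclass
class SectionedRoi:
    """An ROI truncated to the analysis extent and split into sections.

    ``section_of_position[p]`` gives the 1-based section of 1-based position
    ``p+1``; positions beyond the ROI's extent are flagged missing.
    """

    roi: Roi
    n_slices: int
    section_mm: int
    incomplete: bool
    missing_positions: list

    @property
    def sections(self) -> list[int]:
        return [1 + p // self.section_mm for p in range(self.n_slices)]

    def rows(self, fa_map: np.ndarray | None = None) -> list[dict]:
        """One record per analysis position (slice), with mean FA if a map is given."""
        out = []
        for p in range(self.n_slices):
            y = self.roi.start_slice + p
            sel = self.roi.selections[p] if p < self.roi.n_slices else []
            rec = {
                "position": p + 1,
                "section": 1 + p // self.section_mm,
                "slice": y,
                "n_voxels": len(sel),
                "missing": (p + 1) in self.missing_positions or not sel,
            }
            if fa_map is not None:
                rec["fa"] = (
                    float(np.mean([fa_map[v] for v in sel])) if sel else np.nan
                )
            out.append(rec)
        return out


def truncate_and_section(roi: Roi, n_slices: int = 15,
                         section_mm: int = 5) -> SectionedRoi:
    """Keep the ``n_slices`` most anterior slices, split into 5 mm sections.

    At 1 mm slice thickness five slices make one 5 mm section; a shorter ROI
    is kept with its absent positions flagged missing (never an error).
    """
    kept = list(roi.selections[:n_slices])
    missing = [p + 1 for p in range(n_slices)
               if p >= len(kept) or not kept[p]]
    trimmed = Roi(
        method=roi.method, side=roi.side, start_slice=roi.start_slice,
        selections=kept, rater_id=roi.rater_id, scan_id=roi.scan_id,
        repeat_id=roi.repeat_id,
    )
    return SectionedRoi(
        roi=trimmed, n_slices=n_slices, section_mm=section_mm,
        incomplete=bool(missing), missing_positions=missing,
    )


def tract_neighborhood(truth: GroundTruth, dilation: int = 2) -> np.ndarray:
    """Dilated true tube mask standing in for the rater's visual identification."""
    core = truth.occupancy_map > 0.25
    return ndimage.binary_dilation(core, iterations=dilation)
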