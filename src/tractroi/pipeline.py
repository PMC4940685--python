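"""Orchestration of the full synthetic study.

Runs subjects x methods x raters x repeats (plus the repeat-scan arm on one
subject) end to end: phantom generation, resampling to 1 mm, tensor fitting,
skeletonization, tractography, all four ROI definitions, and the statistics.
Every stochastic stage is seeded from ``master_seed`` through a recorded key
tuple, so rerunning a configuration reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tractroi.dwi_model import fit_tensor, mean_b0, resample_isotropic, TensorField
from tractroi.phantom import (
    AXIS_AP,
    AXIS_IS,
    GroundTruth,
    PhantomSpec,
    T1wContrast,
    default_control_points,
    generate_phantom,
    make_t1w_contrast,
    repeat_scan,
    rng_from_keys,
)
from tractroi.roi_methods import (
    METHODS,
    RaterModel,
    Roi,
    find_anterior_limit,
    roi_from_skeleton,
    roi_from_tracking,
    roi_manual,
    tract_neighborhood,
    truncate_and_section,
)
from tractroi.skeleton import SkeletonMask, skeletonize_fa
from tractroi.stats import (
    compare_methods,
    interscan_variability,
    jaccard,
    reliability_by_position,
    section_summaries,
    startpoint_correct_table,
)
from tractroi.tracking import TrackingConfig, track


def default_raters() -> list[RaterModel]:
    return [
        RaterModel(rater_id="R1", start_slice_jitter_sd=1.0,
                   inplane_jitter_sd=0.5, seed=11),
        RaterModel(rater_id="R2", start_slice_jitter_sd=1.0,
                   inplane_jitter_sd=0.5, seed=22),
    ]


@dataclass
class StudyConfig:
    """Design of the synthetic study (defaults mirror the emulated protocol).

    Twenty subjects, two raters (the first rating twice for the intra-rater
    arm), and one subject scanned six times with repositioning.  Per-subject
    anatomy varies within the configured ranges so between-subject FA
    variance is realistic.
    """

    n_subjects: int = 20
    raters: list = field(default_factory=default_raters)
    n_intrarater_repeats: int = 2
    n_repeat_scans: int = 6
    radius_range_mm: tuple = (1.1, 1.4)
    fa_core_range: tuple = (0.70, 0.80)
    curvature_jitter_mm: float = 1.0
    snr_b0: float = 20.0
    noise_model: str = "rician"
    t1w_offset_mm: float = 1.0
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    master_seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_intrarater_repeats < 1:
            raise ValueError("counts must be >= 1")
        if len(self.raters) < 1:
            raise ValueError("at least one rater is required")

    def sittings(self) -> list[tuple[RaterModel, int]]:
        """(rater, repeat) pairs: the first rater repeats, the others rate once."""
        out = [(self.raters[0], r) for r in range(self.n_intrarater_repeats)]
        out += [(r, 0) for r in self.raters[1:]]
        return out


def subject_spec(cfg: StudyConfig, subject_id: int) -> PhantomSpec:
    """Per-subject phantom: jittered curvature, radius and core FA."""
    rng = rng_from_keys(cfg.master_seed, "subject", subject_id)
    pts = np.asarray(default_control_points(), dtype=float)
    jitter = rng.normal(0.0, cfg.curvature_jitter_mm, (len(pts), 2))
    pts[:, 0] += jitter[:, 0]
    pts[:, 2] += jitter[:, 1]
    return PhantomSpec(
        tract_radius_mm=float(rng.uniform(*cfg.radius_range_mm)),
        centerline_control_points=pts.tolist(),
        fa_core=float(rng.uniform(*cfg.fa_core_range)),
        snr_b0=cfg.snr_b0,
        noise_model=cfg.noise_model,
        t1w_offset_mm=cfg.t1w_offset_mm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


@dataclass
class SubjectImages:
    """Everything derived from one scan of one subject on the 1 mm grid."""

    spec: PhantomSpec
    truth: GroundTruth
    tensors: TensorField
    b0_map: np.ndarray
    t1w: T1wContrast
    skeleton: SkeletonMask
    neighborhood: np.ndarray


def process_subject(spec: PhantomSpec, scan_index: int | None = None) -> SubjectImages:
    """Generate (or re-scan) one phantom and compute all derived images."""
    if scan_index is None:
        data, truth = generate_phantom(spec)
    else:
        data, truth = repeat_scan(spec, scan_index)
    data_1mm = resample_isotropic(data, 1.0)
    tensors = fit_tensor(data_1mm)
    return SubjectImages(
        spec=spec,
        truth=truth,
        tensors=tensors,
        b0_map=mean_b0(data_1mm),
        t1w=make_t1w_contrast(truth, spec),
        skeleton=skeletonize_fa(tensors.fa_map),
        neighborhood=tract_neighborhood(truth),
    )


def _tracking_masks(images: SubjectImages, start_slice: int, side: str,
                    rater: RaterModel, subject_key: int, repeat_key: int,
                    fa_stop: float):
    """Seed voxel (rater-placed ~5 mm posterior of the chiasm) and masks."""
    truth = images.truth
    shape = truth.grid_shape
    entries = {v[AXIS_AP]: v for v in truth.centerline_voxels[side]}
    seed_y = min(max(entries), max(min(entries), start_slice + 5))
    base = np.asarray(entries[seed_y])
    rng = rater.rng("seedvox", subject_key, repeat_key, side)
    jitter = np.round(rng.normal(0.0, rater.inplane_jitter_sd, 2)).astype(int)
    cand = base + np.array([jitter[0], 0, jitter[1]])
    cand = np.clip(cand, 0, np.asarray(shape) - 1)
    fa = images.tensors.fa_map
    if fa[tuple(cand)] < fa_stop:
        cand = base  # rater re-places an obviously implausible seed
    seed_mask = np.zeros(shape, dtype=bool)
    seed_mask[tuple(cand)] = True

    termination = np.zeros(shape, dtype=bool)
    termination[:, : start_slice + 1, :] = True  # posterior chiasm plane
    post = min(start_slice + 30, shape[AXIS_AP] - 1)
    termination[:, post:, :] = True  # lateral-geniculate-level coronal slab

    tube_z = np.argwhere(truth.occupancy_map > 0.25)
    z_floor = int(tube_z[:, AXIS_IS].min()) - 4 if len(tube_z) else 0
    exclusion = np.zeros(shape, dtype=bool)
    if z_floor > 0:
        exclusion[:, :, :z_floor] = True  # cerebral-peduncle-level axial slab
    exclusion &= ~seed_mask
    termination &= ~seed_mask
    return seed_mask, termination, exclusion


def define_rois(
    images: SubjectImages,
    rater: RaterModel,
    repeat: int,
    tracking_cfg: TrackingConfig,
    subject_key: int,
    scan_id: int = 0,
) -> dict:
    """All four ROIs for both sides in one rater sitting.

    The sitting's anterior limit is found once and reused by every method.
    Returns {(method, side): Roi}.
    """
    start = find_anterior_limit(images.truth, rater, subject_key, repeat)
    fa = images.tensors.fa_map
    rois = {}
    for side in ("right", "left"):
        rois[("manual_b0", side)] = roi_manual(
            images.b0_map, fa, start, rater, side, method="manual_b0",
            subject_key=subject_key, repeat_key=repeat,
        )
        rois[("manual_t1w", side)] = roi_manual(
            images.t1w.volume, fa, start, rater, side, method="manual_t1w",
            subject_key=subject_key, repeat_key=repeat,
        )
        rois[("fa_skeleton", side)] = roi_from_skeleton(
            images.skeleton, fa, start, images.neighborhood, rater, side,
        )
        seed_mask, termination, exclusion = _tracking_masks(
            images, start, side, rater, subject_key, repeat, tracking_cfg.fa_stop
        )
        cfg = replace(
            tracking_cfg,
            seed=int(
                rng_from_keys(
                    tracking_cfg.seed, "probtrack", subject_key, scan_id,
                    rater.seed, repeat, 0 if side == "right" else 1,
                ).integers(0, 2**31 - 1)
            ),
        )
        vis = track(images.tensors, seed_mask, termination, exclusion, cfg)
        rois[("tractography", side)] = roi_from_tracking(vis, fa, start, side)
    for (method, side), roi in rois.items():
        roi.rater_id = rater.rater_id
        roi.scan_id = scan_id
        roi.repeat_id = repeat
    return rois


def measure_rois(rois: dict, fa_map: np.ndarray, subject: int,
                 scan: int = 0) -> list[dict]:
    rows = []
    for (method, side), roi in rois.items():
        sect = truncate_and_section(roi)
        for rec in sect.rows(fa_map):
            rec.update(
                subject=subject, method=method, side=side,
                rater=roi.rater_id, repeat=roi.repeat_id, scan=scan,
            )
            rows.append(rec)
    return rows


def build_measurement_table(cfg: StudyConfig, progress: bool = False):
    """Run the whole design; returns (table, rois, manifest).

    ``rois`` maps (subject, scan, rater_id, repeat, method, side) -> Roi.
    """
    cfg.validate()
    all_rows: list[dict] = []
    all_rois: dict = {}
    import tractroi

    manifest = {
        "package_version": tractroi.__version__,
        "config": _config_dict(cfg),
        "subjects": {},
    }
    for s in range(cfg.n_subjects):
        spec = subject_spec(cfg, s)
        manifest["subjects"][s] = {"seed": spec.seed,
                                   "fa_core": spec.fa_core,
                                   "tract_radius_mm": spec.tract_radius_mm}
        images = process_subject(spec)
        for rater, rep in cfg.sittings():
            rois = define_rois(images, rater, rep, cfg.tracking, subject_key=s)
            all_rows += measure_rois(rois, images.tensors.fa_map, subject=s)
            for (method, side), roi in rois.items():
                all_rois[(s, 0, rater.rater_id, rep, method, side)] = roi
        if progress:
            print(f"subject {s + 1}/{cfg.n_subjects} done")
        if s == 0 and cfg.n_repeat_scans > 1:
            rater = cfg.raters[0]
            for scan in range(1, cfg.n_repeat_scans + 1):
                images_s = process_subject(spec, scan_index=scan - 1)
                rois = define_rois(images_s, rater, 0, cfg.tracking,
                                   subject_key=s, scan_id=scan)
                all_rows += measure_rois(rois, images_s.tensors.fa_map,
                                         subject=s, scan=scan)
                for (method, side), roi in rois.items():
                    all_rois[(s, scan, rater.rater_id, 0, method, side)] = roi
            if progress:
                print(f"repeat-scan arm ({cfg.n_repeat_scans} scans) done")
    table = pd.DataFrame(all_rows)
    return table, all_rois, manifest


@dataclass
class StudyResult:
    measurements: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: pd.DataFrame
    interrater: dict
    intrarater: dict
    interrater_corrected: dict
    intrarater_corrected: dict
    interscan: dict
    jaccard_table: pd.DataFrame
    rois: dict
    manifest: dict


def _config_dict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=str))


def _method_table(table, method, **filters):
    sub = table[table["method"] == method]
    for col, val in filters.items():
        sub = sub[sub[col] == val]
    return sub


def rater_reliability_tables(table: pd.DataFrame, corrected: bool = False) -> tuple:
    """Per-method inter-rater and intra-rater reliability per position."""
    inter, intra = {}, {}
    base = table[table["scan"] == 0]
    repeating = base.loc[base["repeat"] > 0, "rater"]
    intra_rater = repeating.iloc[0] if len(repeating) else base["rater"].iloc[0]
    for method in sorted(base["method"].unique()):
        inter_tab = _method_table(base, method, repeat=0)
        intra_tab = base[(base["method"] == method)
                         & (base["rater"] == intra_rater)]
        if corrected:
            inter_tab = startpoint_correct_table(inter_tab, factor="rater")
            intra_tab = startpoint_correct_table(intra_tab, factor="repeat")
        inter[method] = reliability_by_position(inter_tab, factor="rater")
        intra[method] = reliability_by_position(intra_tab, factor="repeat")
    return inter, intra


def interscan_tables(table: pd.DataFrame) -> dict:
    """Per-method inter-scan variability per position (repeat-scan arm)."""
    arm = table[table["scan"] > 0]
    out = {}
    for method in sorted(arm["method"].unique()):
        sub = arm[arm["method"] == method]
        rows = []
        for pos, grp in sub.groupby("position"):
            try:
                vc = interscan_variability(grp)
            except ValueError:
                continue
            rows.append(
                {
                    "position": int(pos),
                    "sigma2_scan": vc.sigma2_factor,
                    "sigma2_error": vc.sigma2_error,
                    "total_sigma2": vc.total_sigma2,
                    "interval_halfwidth": 1.96 * np.sqrt(2.0 * vc.total_sigma2),
                }
            )
        out[method] = pd.DataFrame(rows)
    return out


def jaccard_between_methods(rois: dict) -> pd.DataFrame:
    """Pairwise Jaccard of the four methods' analysis ROIs, per subject/side."""
    keys = [k for k in rois if k[1] == 0 and k[3] == 0]  # scan 0, repeat 0
    raters = sorted({k[2] for k in keys})
    first = raters[0]
    rows = []
    subjects = sorted({k[0] for k in keys})
    for s in subjects:
        for side in ("right", "left"):
            for i in range(len(METHODS)):
                for j in range(i + 1, len(METHODS)):
                    a = rois.get((s, 0, first, 0, METHODS[i], side))
                    b = rois.get((s, 0, first, 0, METHODS[j], side))
                    if a is None or b is None:
                        continue
                    ta = truncate_and_section(a).roi
                    tb = truncate_and_section(b).roi
                    rows.append(
                        {
                            "subject": s, "side": side,
                            "method_a": METHODS[i], "method_b": METHODS[j],
                            "jaccard": jaccard(ta, tb),
                        }
                    )
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig, progress: bool = False) -> StudyResult:
    """Execute the full study and all analyses; optionally write ``output_dir``."""
    table, rois, manifest = build_measurement_table(cfg, progress=progress)
    base = table[table["scan"] == 0]
    summaries = section_summaries(base[base["repeat"] == 0])
    comparisons = compare_methods(
        base[(base["repeat"] == 0) & (base["rater"] == cfg.raters[0].rater_id)]
    )
    inter, intra = rater_reliability_tables(table, corrected=False)
    inter_c, intra_c = rater_reliability_tables(table, corrected=True)
    scan_tables = interscan_tables(table) if cfg.n_repeat_scans > 1 else {}
    jac = jaccard_between_methods(rois)
    result = StudyResult(
        measurements=table,
        summaries=summaries,
        comparisons=comparisons,
        interrater=inter,
        intrarater=intra,
        interrater_corrected=inter_c,
        intrarater_corrected=intra_c,
        interscan=scan_tables,
        jaccard_table=jac,
        rois=rois,
        manifest=manifest,
    )
    if cfg.output_dir:
        write_results(cfg.output_dir, result)
    return result


def write_results(out_dir: str, result: StudyResult) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.measurements.to_csv(os.path.join(out_dir, "measurements.csv"), index=False)
    result.summaries.to_csv(os.path.join(out_dir, "section_summaries.csv"), index=False)
    result.comparisons.to_csv(os.path.join(out_dir, "method_comparisons.csv"),
                              index=False)
    result.jaccard_table.to_csv(os.path.join(out_dir, "jaccard.csv"), index=False)
    for name, tabs in (
        ("interrater", result.interrater),
        ("intrarater", result.intrarater),
        ("interrater_corrected", result.interrater_corrected),
        ("intrarater_corrected", result.intrarater_corrected),
        ("interscan", result.interscan),
    ):
        frames = [t.assign(method=m) for m, t in tabs.items() if len(t)]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                os.path.join(out_dir, f"reliability_{name}.csv"), index=False
            )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=1, default=str)


def load_study_config(path: str) -> StudyConfig:
    """Build a StudyConfig from a YAML key-value file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "raters" in raw:
        raw["raters"] = [RaterModel(**r) for r in raw["raters"]]
    if "tracking" in raw:
        raw["tracking"] = TrackingConfig(**raw["tracking"])
    for key in ("radius_range_mm", "fa_core_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)
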