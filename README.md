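# tractroi

Reliability analysis of region-of-interest (ROI) methods for extracting
fractional anisotropy (FA) from small white-matter tracts, on synthetic
diffusion-MRI phantoms with known ground truth.

## The problem

Extracting a diffusion parameter such as FA from a thin structure like the
optic tract is dominated by geometry: the tract is 2–3 mm across, the
acquisition voxels are 2.2 mm, and a one-voxel placement error moves the
measurement from the coherent tract core into partial-volume border tissue.
How an ROI is defined therefore changes both the FA values obtained and how
reproducible they are across raters and repeat scans.

`tractroi` implements four ROI procedures under shared rules (anterior limit
at the most posterior chiasm slice, at most two voxels per coronal slice,
15 analysis slices split into three 5 mm sections):

1. **manual b0** — per slice, the two most central voxels of the tract
   cross-section traced on the b = 0 image;
2. **manual T1W** — the same tracing on an anatomical-contrast image carrying
   a residual misregistration to diffusion space;
3. **FA skeleton** — selection restricted to an individual-space FA skeleton
   (ridge of locally maximal FA, voxels with FA < 0.2 excluded), keeping per
   slice the two highest-FA voxels representing the tract middle;
4. **tractography** — per slice the two highest-FA voxels visited by
   probabilistic streamlines from a rater-placed seed.

Because no real scans ship with the package, a phantom module generates the
whole study: curved mirrored tubes with an anisotropic core
(FA = fa_core, axially symmetric tensor along the local tangent), a
crossing-fiber chiasm analog, partial-volume borders, Rician noise
(b = 0 plus 32 directions at b = 800 s/mm², 2.2 mm voxels resampled to
1 mm), repeat scans with repositioning, and stochastic rater models (start
slice and in-plane jitter) standing in for human raters.

## The statistics

For a measurement table of slice-level FA (subject × method × rater ×
scan × side × slice):

- per-section **mean, SD, CV** over subjects (sides averaged within subject);
- **pairwise method contrasts** per section: paired subject-level differences
  (the generalized-least-squares contrast under compound-symmetric
  within-subject covariance over the five slices of a section), adjusted with
  the Tukey–Kramer studentized-range procedure;
- **variance components** from an expected-mean-squares ANOVA with subject
  and rater random, side fixed, giving the repeatability coefficient
  `RC = 1.96·√2·σ_error` and Bland–Altman limits of agreement
  `d̄ ± 1.96·√2·σ_sum`, where σ_sum collects all rater-containing interaction
  variances plus the error;
- **start-point correction** — re-anchoring compared ROIs at their common
  anterior slice — isolating how much rater variability the start-slice
  choice explains;
- **inter-scan variability** (scan random, side fixed; scan variance summed
  with the error term);
- **Jaccard overlap** |A∩B| / |A∪B| of ROI voxel sets over shared slices.

## Worked example

```python
import numpy as np
from tractroi import (PhantomSpec, generate_phantom, resample_isotropic,
                      fit_tensor, skeletonize_fa, RaterModel,
                      find_anterior_limit, roi_from_skeleton,
                      truncate_and_section)
from tractroi.roi_methods import tract_neighborhood

spec = PhantomSpec(seed=7)          # 2.2 mm acquisition, Rician noise at SNR 20
data, truth = generate_phantom(spec)
data_1mm = resample_isotropic(data, 1.0)
tensors = fit_tensor(data_1mm)
skeleton = skeletonize_fa(tensors.fa_map)          # FA < 0.2 excluded

rater = RaterModel("R1", seed=11)
start = find_anterior_limit(truth, rater)
roi = roi_from_skeleton(skeleton, tensors.fa_map, start,
                        tract_neighborhood(truth), rater, "right")
rows = truncate_and_section(roi).rows(tensors.fa_map)
for sec in (1, 2, 3):
    vals = [r["fa"] for r in rows if r["section"] == sec and not r["missing"]]
    print(f"section {sec}: mean FA {np.mean(vals):.3f} over {len(vals)} slices")
```

prints

```
section 1: mean FA 0.486 over 5 slices
section 2: mean FA 0.383 over 5 slices
section 3: mean FA 0.363 over 5 slices
```

Section 1 sits at the chiasm analog where crossing fibers mix; sections 2–3
follow the tract body, where the measured FA (≈ 0.4 at this noise level) is
well below the construction FA of 0.75 — the partial-volume dilution of a
2–3 mm tract sampled at 2.2 mm, which is exactly the effect the study design
probes.

## The full study

Numbered drivers under `analysis/` reproduce the complete experiment and
write tables to `results/study/`:

```sh
python analysis/01_run_study.py           # 20 subjects, raters, repeat scans (~2 min)
python analysis/02_method_comparison.py   # section summaries + Tukey contrasts
python analysis/03_rater_reliability.py   # RC / limits of agreement per position
python analysis/04_interscan_variability.py
python analysis/05_jaccard_overlap.py
```

Every stochastic stage is seeded from the study config's `master_seed`;
rerunning a configuration reproduces every number, and `manifest.json`
records all seeds and parameters.

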