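# Methods

This note records the models behind `tractroi`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic experiments
can and cannot say about real data.

## Coordinate convention

Everything uses 0-based voxel indices with axis 0 = right–left, axis 1 =
anterior–posterior (index 0 anterior-most), axis 2 = inferior–superior.
A *coronal slice* is a fixed index on axis 1. Voxel centers sit at
`index × voxel_size` in one shared mm frame for the 2.2 mm acquisition grid
and the 1 mm analysis grid, so the two grids share their origin voxel
center. Sides are split at the mid-sagittal column of the analysis grid;
"right" is the lower-index half.

## Phantom

The tract analog is a pair of mirrored tubes defined by a cubic-spline
centerline running mainly anterior→posterior, bending gently in-plane.
Defaults (all configurable on `PhantomSpec`):

| parameter | default | rationale |
|---|---|---|
| voxel size | 2.2 mm | clinical whole-brain DTI protocol emulated |
| directions / b | 32 at 800 s/mm², 6 × b=0 | same protocol |
| tube radius | 1.25 mm | a 2–3 mm tract diameter |
| fa_core | 0.75 | coherent white-matter core |
| md_core / md_background | 0.8 / 1.0 ×10⁻³ mm²/s | white matter vs mixed surround |
| SNR at b=0 | 20 | 1.5 T acquisition with signal averaging |
| noise | Rician (magnitude of complex Gaussian) | standard MR magnitude model; σ = S0_tube/SNR |
| t1w offset | 1.0 mm (1.5 mm in the study runs) | residual misregistration of an anatomical image warped to diffusion space; the study condition uses the middle of the plausible 1–2 mm band |

Inside the tube the tensor is axially symmetric along the local centerline
tangent with eigenvalues solving FA = fa_core and MD = md_core
(λ₁ = MD(1+2a), λ₂,₃ = MD(1−a), a = FA/√(3−2FA²)). Border voxels mix tube
and background tensors by sub-voxel occupancy (5³ samples per acquisition
voxel, 3³ on the 1 mm truth grid). Anterior of the designated chiasm slice
the two tubes converge to the midline and overlap; overlap sub-samples
average the two sides' tensors, so crossing-fiber mixing depresses FA there
and the apparent structure widens — giving the "most posterior chiasm" rule
a detectable correlate and making the most anterior section naturally
low-FA. The tube tapers (40 % radius loss) over its posterior half only, so
the 15-slice analysis window keeps a stable cross-section while the
manual-tracing stop rule ("no longer separable") has something real to
detect posteriorly.

Partial volume is the dominant realistic feature: a 2.5 mm tube sampled at
2.2 mm yields measured core FA near 0.4–0.6 that beats against the voxel
grid along the tract. The phantom does **not** model EPI distortion, eddy
currents, within-scan motion, CSF pulsation, or anatomically heterogeneous
neighborhoods (adjacent anisotropic bundles); passing tests show that the
procedures behave as specified under controlled geometry, not that their
effect sizes match any particular scanner or anatomy.

Repeat scans re-generate the phantom after a small rigid repositioning
(translation sd 0.5 mm per axis, rotation sd 1° about two axes) with fresh
noise, both seeded by (subject seed, scan index); fields are evaluated at
back-transformed points and tangents rotated forward, so ground truth stays
exact. The analysis then proceeds on the first-scan grid without estimating
a registration: the simulator knows the alignment exactly, and estimating it
would test a registration library rather than the ROI methods.

The T1W-like contrast is the tube occupancy image displaced by a smooth
field: constant magnitude `t1w_offset_mm`, direction perpendicular to the AP
axis and slowly rotating along the tract, phase drawn from the subject seed.
ROIs traced on it inherit the displacement — the mechanism by which the
manual-T1W method reads border voxels.

## Tensor fit and resampling

Diffusion volumes are interpolated to 1 mm isotropic with cubic B-splines
(a sinc-like kernel; values outside the source grid are zero, negative
spline overshoot clipped to zero signal) *before* fitting, matching the
emulated pipeline's processing order. The tensor is fitted by ordinary
least squares on log-signals; weighted variants were not implemented because
the reference pipeline's behavior is unspecified and OLS is the simplest
defensible choice. Negative eigenvalues are clamped to zero and flagged
before FA. The fit is exact on noiseless single-tensor voxels for any
non-degenerate ≥ 6-direction scheme, which the tests exploit as an oracle.

## FA skeleton

Per subject, in native 1 mm space (no common-space registration or group
skeleton): a candidate voxel is kept when its FA is a local maximum along
the direction perpendicular to the local tract, compared against the two
linearly interpolated samples one voxel away along that direction; voxels
with FA < 0.2 are then removed.

*Perpendicular direction.* Where the smoothed FA gradient (Gaussian,
σ = 1 voxel) exceeds 0.03 FA/voxel the gradient itself is used — off the
ridge top it points at the tract center, so off-axis voxels fail the test
against their up-gradient neighbor and the skeleton stays one voxel thin.
On the ridge top, where the gradient vanishes, the eigenvector of the most
negative Hessian eigenvalue of the smoothed map is used, with a gradient
fallback when the two most negative Hessian eigenvalues are within 10 % of
each other (ambiguous curvature).

*Tie-breaking.* The comparison is strict along the positive perpendicular
direction and non-strict along the negative one (ε = 10⁻⁶, direction sign
canonicalised to the first non-zero component), so a flat two-voxel ridge
top keeps exactly one voxel and a constant map yields an empty skeleton.
This replaces an interpolated center-of-gravity plateau rule with a simpler
deterministic construction that selects the same ridge voxels on all tested
geometries.

## Tractography surrogate

A desk-scale stand-in for sampled-posterior probabilistic tracking:
streamlines follow the principal eigenvector of the trilinearly interpolated
tensor (recomputed at the interpolated tensor), sign-aligned with the
previous step, perturbed each step by a rotation of Gaussian angle about a
random perpendicular axis. Defaults: 1000 streamlines per seed voxel,
0.5 mm steps, 10° dispersion, 45° per-step curvature limit, FA stop 0.1,
300 step cap, bidirectional from a single rater-placed seed ~5 mm posterior
of the chiasm. Termination masks sit at the chiasm plane and a posterior
coronal slab; an axial exclusion slab lies inferior to the tract, and any
streamline touching it is discarded entirely. The fixed angular dispersion
deliberately does not model how orientation uncertainty widens in low-SNR
border voxels; consequently the surrogate's visitation maps hug the tract
more faithfully than a sampled ball-and-stick posterior would, and the
tractography ROI behaves more like the b0 ROI here than it may on real
data. With dispersion 0 the walk is fully deterministic (the RNG is never
consulted).

## Rater models

A rater contributes (i) a rounded-Gaussian start-slice jitter (sd 1 slice),
(ii) an in-plane Gaussian jitter of the cross-section centroid (sd 0.5 mm)
for the manual methods and the tracking seed, and (iii) optionally a
soft-max selection temperature (default 0, deterministic). Each draw is
keyed by (rater seed, subject, repeat, method, side), so one rater's sitting
reuses its start slice across all four methods, repeats differ, and reruns
reproduce bit-for-bit. The "no longer separable" stopping rule for manual
tracing is a contrast-to-noise criterion: segmentation threshold at 40 % of
peak-over-background within the hemifield, largest connected component,
noise from a robust MAD of sub-threshold voxels, stop after two consecutive
slices with CNR < 1 (a noiseless image never triggers it and stops at the
first empty cross-section). The skeleton method restricts candidates to a
2-voxel dilation of the true tube — the stand-in for the rater recognising
which skeleton branch is the tract — so its rater dependence is essentially
the start slice, which is what its reliability results then show.

The single-voxel rule (a one-voxel cross-section yields a one-voxel
selection) is applied uniformly across methods, as the global two-voxel
maximum implies.

## Statistics

*Section summaries.* FA is averaged within section and across sides per
subject, then mean, SD (ddof = 1) and CV = SD/mean (percent) are taken over
subjects.

*Method contrasts.* Per section, per method pair: paired subject-level
differences of section means. On a balanced design this equals the
generalized-least-squares contrast under a compound-symmetric
within-subject covariance over the section's five slices, and each pair
carries its own variance ("paired t-test with unequal variances").
Adjustment uses the studentized range with k = number of methods
(q = √2·|t|, df = n−1); with two groups it reduces exactly to the
unadjusted paired test. Critical values are memoized because
`studentized_range.ppf` is expensive.

*Variance components.* Balanced three-factor ANOVA (subject random, rater or
repeat or scan random, side fixed; one observation per cell, so the
three-way interaction is the error) solved by unrestricted-model expected
mean squares — closed-form and oracle-checkable, in contrast to REML.
Negative estimates are truncated to zero with a warning; the untruncated
values are kept (`sigma2_raw`) because they are the unbiased quantities for
Monte-Carlo averaging. Note the two-level rater main effect has a single
degree of freedom: its single-run estimate is inherently volatile no matter
how many subjects are scanned, and only its expectation is testable.
Derived quantities: repeatability coefficient 1.96·√2·σ_error; limits of
agreement d̄ ± 1.96·√2·σ_sum with σ_sum² the sum of all rater-containing
interaction components plus error. Whether the rater *main* effect joins
σ_sum is ambiguous in the underlying definition; the default excludes it
(the literal reading), and `include_main_effect=True` adds it.

*Start-point correction.* Compared ROIs are re-anchored at the most anterior
slice present in both; positions and sections renumber from there. Only
meaningful for repeated definitions on the same dataset, never across
subjects or scans.

*Inter-scan variability.* Scan (random) × side (fixed) two-way ANOVA on the
repeatedly scanned subject; the scan variance is summed with the error term
to a total σ², reported as 1.96·√2·√total intervals.

*Jaccard.* |A∩B| / |A∪B| restricted to the slices included in both ROIs;
an empty restricted union is undefined (NaN with a warning).

*Normality.* The visual Q-Q inspection of the emulated workflow is replaced
by an advisory Shapiro–Wilk report; nothing is gated on it.

*Missing data.* A slice missing in one rating (skeleton gap, short ROI)
enters the table as NaN and drops that subject from the affected position's
ANOVA (complete-case); a structurally absent design cell is rejected with
the offending cell named.

## Study design and problem sizes

The default study is 20 subjects (per-subject draws: radius U(1.1, 1.4) mm,
core FA U(0.70, 0.80), centerline control-point jitter sd 1 mm — enough
between-subject variance to exercise the CV and the covariance model), two
raters with identical jitter sds and distinct seeds, a second sitting by the
first rater two "months" apart (a fresh repeat key), and one subject scanned
six times. Grid 24×32×12 at 2.2 mm (53×70×26 at 1 mm), giving ≈ 54 tract
slices beyond the chiasm — comfortably more than the 15 analyzed. A full
study runs in about two minutes on one CPU; the test suite uses a 4-subject
version of the same design plus single-purpose phantoms, and the calibration
simulations use 200 synthetic subjects (variance recovery) and 500 null
replicates (type-I error of the adjusted comparisons).

## Known limitations

- The surround is isotropic; real tracts border CSF on one side and other
  white matter on the other, which shifts partial-volume FA asymmetrically.
- The fixed-dispersion tracking surrogate understates orientation
  uncertainty in border voxels (see above).
- REML variance components and unstructured within-section covariance are
  not implemented; the method-of-moments/compound-symmetry defaults are the
  analysis actually reported.
- Rater behavior is reduced to start-slice and centroid jitter; systematic
  rater bias (one rater consistently anterior) is representable only through
  the seeds, not as an explicit parameter.
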