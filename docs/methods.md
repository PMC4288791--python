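# Methods

## Model and assumptions

The boundary shift integral estimates the volume swept by a structure
boundary between two time points by integrating clipped intensity
differences over a region that straddles the boundary. The estimate is
accurate when (i) both images live on one grid with equal
interpolation-related blurring (the half-way space; registration is out of
scope and inputs are trusted to be pre-registered), (ii) the two images
share one intensity scale after normalization, and (iii) the clipping
window lies strictly between the mean intensities of the tissues flanking
the boundary, so the clip profile transitions fully inside the region.
Under those conditions the per-column integral of `clip(I_A) − clip(I_B)`
equals the local boundary displacement, and the sum times the voxel volume
is the volume change.

Sign convention: positive BSI/PBVC is loss from baseline to repeat. On T1
contrast (CSF < GM < WM) atrophy at a tissue–CSF border makes the baseline
brighter inside the region. For two-border (hippocampus-style) structures
the GM–WM term is negated before summation, because loss at that border
brightens the *repeat*; the sign is forced by the contrast ordering and is
verified against a two-border phantom with closed-form shell volumes.

## Pipeline stages and parameters

All defaults form one fixed parameter set, logged on every run; deviations
are logged at warning level.

| Stage | Parameter | Default | Why |
|---|---|---|---|
| DBC | kernel radius | 5 voxels | standard kernel for differential bias; large enough to be anatomy-blind, small enough to track smooth fields |
| k-means | mask dilations | 3 (6-connected) | brings enough CSF into the estimation region for a stable CSF cluster |
| k-means | clusters | 3 (CSF/GM/WM) + separately computed interior mean | the interior region is treated as a fourth regression point, not a fourth cluster |
| binary XOR | dilations/erosions | 1/1 | minimal reading of "dilated union, eroded intersection" |
| fuzzy region | η, ζ, n_e, n_d | 0.95, 0.90, 0, 1 | the published parameterization of the fuzzy variant |
| binarization | threshold | 0.5, ties inside | a uniform-0.5 mask binarized at 0.5 is full |
| morphology | connectivity | 6 (face-adjacent); 26 available | smallest isotropic structuring element |

### Differential bias correction

Residual smooth intensity differences between time points masquerade as
boundary shift. The differential field is modeled multiplicatively:
`d = log(baseline) − log(repeat)` is median-filtered over the cubic
(Chebyshev) neighborhood of half-width 5 inside the estimation mask (the
0.5-binarized union of both masks, dilated 3), and the correction
`exp(∓d̃/2)` is split equally so neither time point is privileged and the
per-voxel geometric mean is preserved. The median (not the mean) is
essential: genuine anatomical change contributes large-magnitude, spatially
compact log-differences that a mean would smear into the correction.

The masked median (out-of-mask voxels excluded from every neighborhood) is
computed by a streaming histogram: 512 bins over the in-mask range, per-bin
cumulative box sums (three running cumsums each), and per-voxel detection
of the two central rank crossings, averaged. Quantization error is at most
one bin width, i.e. (max−min)/512 of the log-difference — ~4·10⁻⁴ for a
±10% bias field — which is negligible against the fields being corrected;
the averaged two-rank definition keeps the filter antisymmetric under
swapping the time points. Constant fields short-circuit to exact values.

### Tissue statistics and normalization

A deterministic 1-D Lloyd k-means (k = 3) runs on the intensities inside
the dilated mask: centers start at the 10th/50th/90th intensity
percentiles, iteration stops when no assignment changes (cap 300). Seeding
from fixed percentiles makes the result reproducible without randomness,
and labeling clusters by ascending mean makes the CSF/GM/WM assignment
independent of internal cluster order. The repeat image is mapped onto the
baseline intensity scale by ordinary least squares through four paired
points (CSF, GM, WM, interior means); the interior mean comes from the
once-eroded binarized mask, which strips the partial-volume rim. The
clipping window uses tissue statistics averaged across time points —
equivalent, under the linear window formulas, to averaging the two
windows' bounds. For small structures, tissue statistics are estimated
inside the dilated structure mask itself, so the flanking CSF and WM are
represented in the clusters.

### Degenerate inputs and ties

Identical masks make every region variant empty; by contract this yields
BSI = 0, not an error. A pXOR value exactly equal to κ receives weight 1
(the strict inequality in the weighting rule is honored). A window with
low ≥ high raises a window-collapse error naming the border — it signals
tissue distributions too overlapped for boundary integration. Masks may
overshoot [0, 1] by ≤ 10⁻³ (resampling artifacts, clamped); larger
violations are rejected as wrong files rather than rescaled.

## The phantom generator

The phantom emulates the study inputs — a T1-like pair in half-way space
with probabilistic masks and a known interval — as nested ellipsoids:
CSF background (intensity 20), GM shell (100), WM core (160), defaults
96³ voxels at 1 mm, outer semi-axes 30/26/22 mm, core 18/15/12 mm.
Atrophy scales every semi-axis by `(1−f)^(1/3)`, so the structure volume
drops by exactly `f` and the truth stays closed-form, `V = 4/3·π·abc`.
Boundary voxels carry analytic partial volume (inside-fraction by 4×
supersampling), so the probabilistic mask integrates to the analytic
volume to within rasterization error (<0.5% at 1 mm). Options: additive
Gaussian noise (both images), a smooth polynomial multiplicative bias
field applied to the repeat only (so the effect of DBC is directly
measurable), optional extra Gaussian blur (`pv_sigma`), and a
hippocampus-style mode where the mask is the GM shell bordered by CSF
outside and WM inside. Intervals default to 1 year so PBVC equals percent
volume change.

What the phantom does *not* model: cortical folding and closed sulci,
anisotropic or spatially varying atrophy, registration/interpolation blur,
Rician noise. Passing phantom tests therefore demonstrates correct
integration of a uniform boundary shift under ideal segmentations, not
performance on cohort data.

### Known limitation: behavior under resolution refinement

Because the phantom's partial-volume ramp is always exactly one voxel wide
by construction, refining the grid sharpens the mask ramp *in physical
units*. The adaptive gain κ (mean of nonzero pXOR) then rises — the
boundary shift grows relative to the voxel — which narrows the weight-1
band of the region, while the k-means tissue SDs (purely partial-volume
driven on a noiseless phantom) shrink and widen the clipping window in
probability units. The net effect is that the window-averaged region
weight falls, and the measured gBSI moves slightly *away* from truth as
resolution increases within the sub-voxel-shift regime (measured on the
noiseless 2% phantom: −1.4% of truth at 1 mm, −2.6% at 0.5 mm, −4.3% at
0.25 mm; the binary-XOR variant shows the same trend at +0.2% → +0.5%).
This is the documented periphery down-weighting of the probabilistic
region — the same mechanism that makes gBSI report slightly lower atrophy
rates than the binary variant on real cohorts — interacting with a phantom
whose ramp width is resolution-dependent, not an integration error; with a
fixed physical ramp (e.g. interpolation blur, as real half-way-space data
have) the window and κ would be resolution-stable. All errors remain far
inside the 15% recovery band.

## Trial statistics

The sample-size formula keeps 0.841 (80% power) and 1.96 (two-sided 5%)
as literal constants so the arithmetic matches the printed convention
digit-for-digit; `(0.841+1.96)² = 7.845601`. Under "controlling for normal
aging" the effect Δ is the reduction times the patient-minus-control mean
difference while σ remains the patient-group SD — the trial arms are
patients; controls only shift the detectable effect. Reported sample sizes
are rounded to the nearest integer with the unrounded value retained; when
reproducing published tables from means/SDs printed to 2 decimals, cells
can differ by up to ±2 from input rounding alone.

The bias-corrected bootstrap resamples subjects with replacement within
each group (patients only when no control group is supplied), recomputes
the sample size per replicate, and reads the interval at the
bias-corrected percentiles Φ(2z₀ ± 1.96) with z₀ from the fraction of
replicates below the point estimate. Replicates whose resampled effect is
non-positive (possible when the groups' resampled means cross) are scored
as +∞ so percentiles stay well defined; zero-variance replicates score 0.
Constant-valued groups collapse the interval to the point estimate.

## Problem sizes used in the test suite

Unit tests run phantoms at 40³/2 mm; the end-to-end recovery checks run
the default 96³/1 mm phantom at four atrophy levels plus one 192³/0.5 mm
refinement, and the bootstrap checks use 10,000 replicates — the same
replicate count as the published analysis.
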