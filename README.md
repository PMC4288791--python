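# gbsi — generalized boundary shift integral

Longitudinal atrophy measurement for brain MRI (and small structures such
as the hippocampus) from pairs of co-registered 3D scans with probabilistic
segmentations, plus the clinical-trial sample-size statistics used to
evaluate such biomarkers.

## Who this is for

Neuroimaging groups measuring structural change between a baseline and a
repeat T1-weighted scan. The inputs are assumed to be already resampled
into a common half-way space (symmetric registration is a separate,
upstream step), each with a probabilistic region mask in `[0, 1]` on the
same grid — e.g. the output of a multi-atlas label-fusion segmentation.

## The method

The boundary shift integral (BSI) measures volume change by integrating
clipped intensity differences over a region straddling the structure
boundary:

    BSI = D · Σ_xyz  R(x,y,z) · ( clip(I_A) − clip(I_B) )

where `D` is the voxel volume (mm³), `I_A`/`I_B` are the normalized
baseline/repeat intensities, `clip(I) = (min(max(I, I_low), I_high) −
I_low)/(I_high − I_low)` maps intensities into `[0, 1]` over the clipping
window, and `R` is the boundary-region weight field. Positive BSI is volume
loss (on T1 contrast, tissue turning into CSF makes the baseline brighter
inside the region).

The *generalized* BSI (gBSI) builds `R` from the probabilistic masks
directly. With `Ā = 1 − A`:

    pXOR(A,B) = A·B̄ + Ā·B − (A·B̄)(Ā·B)
    R(x) = pXOR(x)/κ   if pXOR(x) < κ,   else 1

with the gain factor `κ` set adaptively to the mean of the nonzero pXOR
values. With κ = 1 and binary masks this reverts exactly to the classic
binary XOR region. The package also provides the classic region (dilated
union minus eroded intersection of the 0.5-binarized masks, "KN-BSI") and
the fuzzy variants pBSI₁/pBSI_γ (thresholded fuzzy union/intersection,
weighted by `max(γ, (A+B)/2)`) for comparison.

The full pipeline: symmetric differential bias correction (median-filtered
log-intensity difference, kernel radius 5) → k-means (k = 3) CSF/GM/WM
intensity estimation and linear-regression normalization of the repeat
onto the baseline scale → automatic clipping window
`[CSF mean + SD, GM mean − SD]` averaged across time points (plus a second
`[GM mean + SD, WM mean − SD]` window for hippocampus-style two-border
structures) → region construction → integral → annualized percentage
volume change (PBVC = 100·BSI / binarized-baseline-mask volume / scan
interval).

For trial planning, the per-arm sample size to detect a fractional
reduction of disease progression (80% power, two-sided 5% test) is

    n = (0.841 + 1.96)² · 2σ² / Δ²

with Δ the treated-vs-placebo difference in mean annualized PBVC and σ the
patient-group SD; bias-corrected bootstrap confidence intervals are
computed by within-group resampling.

## Worked example

Generate a synthetic phantom pair with exactly 2% annual volume loss and
measure it:

```sh
gbsi phantom --outdir demo --grid 96 --voxel-size 1.0 --atrophy 0.02 --seed 7
gbsi bsi demo/baseline.nii.gz demo/repeat.nii.gz \
         demo/baseline_mask.nii.gz demo/repeat_mask.nii.gz \
         --report demo/report.json
```

which prints (abridged):

```json
{
  "bsi_mm3": 1418.7752577786146,
  "pbvc_percent_per_year": 1.9711782507761122,
  "variant": "pxor_gbsi",
  "windows": [[33.19247608170116, 93.29629832231755]],
  "kappa": 0.2514291230732009,
  "region_voxels": 10848,
  "baseline_volume_mm3": 71976.0
}
```

The phantom's true loss is 1437.1 mm³ (2.000 %/yr); gBSI recovers
1418.8 mm³ (1.971 %/yr), a 1.4% relative error, with the adaptive gain
κ ≈ 0.25 and the automatically selected intensity window [33.2, 93.3]
sitting between the phantom's CSF (20) and GM (100) intensities.

The same from Python:

```python
from gbsi import PhantomSpec, make_phantom, run_bsi, PipelineConfig

pair, truth = make_phantom(PhantomSpec(atrophy_fraction=0.02))
result = run_bsi(pair, PipelineConfig())
print(result.pbvc_percent_per_year)   # 1.9711782507761122
```

Sample sizes from a per-subject PBVC table (`subject,group,pbvc` columns):

```sh
gbsi samplesize pbvc.csv --control-group CN --n-boot 10000 --seed 1
```

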