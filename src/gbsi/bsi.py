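"""The boundary shift integral: clipping, integration, PBVC, full pipeline.

The integral over one clipping window [I_low, I_high] is

    BSI = D * sum_xyz R(x,y,z) * (clip(I_A) - clip(I_B))

with D the voxel volume (mm^3), R the boundary-region weights and
``clip(I) = (min(max(I, I_low), I_high) - I_low) / (I_high - I_low)``.
The sign convention is: positive BSI = volume loss from baseline to repeat
(on T1 contrast, tissue turning into CSF makes the baseline brighter inside
the region).

For small GM structures bordered by both CSF and WM (hippocampus) a double
window is used: the CSF–GM integral plus the *negated* GM–WM integral —
at the GM–WM border structure loss makes the repeat brighter, so the raw
integral there is negative and the negation makes loss count positively at
both borders.

``run_bsi`` chains the full pipeline: DBC -> tissue normalization ->
window selection -> region construction -> integral -> PBVC.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import boundary_regions as br
from . import diff_bias, tissue_norm
from .config import PipelineConfig
from .errors import DegenerateInputError, DegenerateRegionError, GridError, StageError
from .tissue_norm import IntensityWindow
from .volumes import ProbMask, ScanPair, VolumeGrid, binarize

__all__ = [
    "BSIResult",
    "clip",
    "integrate",
    "contribution_map",
    "integrate_double_window",
    "pbvc",
    "run_bsi",
]


@dataclass
class BSIResult:
    """Outcome of one BSI run plus diagnostics for reproducibility."""

    bsi_mm3: float
    pbvc_percent_per_year: float
    variant: str
    windows: tuple
    kappa: Optional[float]
    region_voxels: int
    baseline_volume_mm3: float
    interval_years: float
    norm_slope: float = 1.0
    norm_intercept: float = 0.0
    contributions: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "bsi_mm3": self.bsi_mm3,
            "pbvc_percent_per_year": self.pbvc_percent_per_year,
            "variant": self.variant,
            "windows": [[w.low, w.high] for w in self.windows],
            "kappa": self.kappa,
            "region_voxels": self.region_voxels,
            "baseline_volume_mm3": self.baseline_volume_mm3,
            "interval_years": self.interval_years,
            "norm_slope": self.norm_slope,
            "norm_intercept": self.norm_intercept,
        }


def clip(values, window: IntensityWindow):
    """Map intensities into [0,1] over the window: 0 below low, 1 above high."""
    v = np.asarray(values, dtype=float)
    out = (np.minimum(np.maximum(v, window.low), window.high) - window.low) / window.width
    return out if out.ndim else float(out)


def contribution_map(
    baseline: VolumeGrid,
    repeat: VolumeGrid,
    region: br.BoundaryRegion,
    window: IntensityWindow,
) -> np.ndarray:
    """Per-voxel signed contribution D*R*(clip(I_A)-clip(I_B)), mm^3."""
    if not baseline.same_grid(repeat):
        raise GridError("baseline and repeat are not on one grid")
    if region.weights.shape != baseline.shape:
        raise GridError("region is not on the image grid")
    diff = clip(baseline.data, window) - clip(repeat.data, window)
    return baseline.voxel_volume * region.weights * diff


def integrate(
    baseline: VolumeGrid,
    repeat: VolumeGrid,
    region: br.BoundaryRegion,
    window: IntensityWindow,
) -> float:
    """The boundary shift integral over one window, signed mm^3."""
    return float(contribution_map(baseline, repeat, region, window).sum())


def integrate_double_window(
    baseline: VolumeGrid,
    repeat: VolumeGrid,
    region: br.BoundaryRegion,
    window_csf_gm: IntensityWindow,
    window_gm_wm: IntensityWindow,
) -> float:
    """Two-border integral: CSF–GM term minus the GM–WM term (see module doc)."""
    term_csf = integrate(baseline, repeat, region, window_csf_gm)
    term_wm = integrate(baseline, repeat, region, window_gm_wm)
    return term_csf - term_wm


def pbvc(
    bsi_mm3: float,
    baseline_mask: ProbMask,
    interval_years: float,
    voxel_volume: float,
    threshold: float = 0.5,
) -> float:
    """Annualized percentage volume change.

    ``100 * BSI / (binarized baseline mask volume) / interval``; positive
    values are loss, matching the BSI sign convention.
    """
    if interval_years <= 0:
        raise DegenerateInputError("interval_years must be > 0")
    n = int(binarize(baseline_mask, threshold).prob.sum())
    if n == 0:
        raise DegenerateInputError("binarized baseline mask is empty")
    return 100.0 * bsi_mm3 / (n * voxel_volume) / interval_years


def _build_region(
    A: ProbMask, B: ProbMask, config: PipelineConfig
) -> br.BoundaryRegion:
    if config.variant == "pxor_gbsi":
        return br.gbsi_region(A, B, kappa_override=config.kappa_override)
    if config.variant == "binary_xor":
        return br.binary_xor_region(
            A,
            B,
            n_dilate=config.xor_dilate,
            n_erode=config.xor_erode,
            threshold=config.binarize_threshold,
            connectivity=config.connectivity,
        )
    params = br.PbsiParams(
        eta=config.pbsi_eta,
        zeta=config.pbsi_zeta,
        n_erode=config.pbsi_n_erode,
        n_dilate=config.pbsi_n_dilate,
        gamma=1.0 if config.variant == "pbsi_1" else config.pbsi_gamma,
        combine=config.pbsi_combine,
    )
    return br.pbsi_region(A, B, params, connectivity=config.connectivity)


def run_bsi(
    pair: ScanPair,
    config: Optional[PipelineConfig] = None,
    keep_contributions: bool = False,
) -> BSIResult:
    """Run the full pipeline on a registered scan pair.

    Stages (each error is re-raised tagged with its stage name):
    DBC (optional) -> k-means tissue statistics & normalization of the
    repeat onto the baseline scale -> averaged intensity window(s) ->
    boundary region (per ``config.variant``) -> integral -> PBVC.

    Identical masks yield an empty region and a BSI of exactly 0 rather
    than an error.
    """
    config = config or PipelineConfig()
    baseline, repeat = pair.baseline, pair.repeat

    if config.dbc:
        try:
            union = ProbMask(
                prob=np.maximum(pair.baseline_mask.prob, pair.repeat_mask.prob),
                grid=baseline,
            )
            dbc_mask = tissue_norm.kmeans_region(
                union, dilations=config.kmeans_dilations, connectivity=config.connectivity
            )
            baseline, repeat = diff_bias.differential_bias_correct(
                baseline,
                repeat,
                diff_bias.DbcParams(mask=dbc_mask, kernel_radius=config.dbc_kernel_radius),
            )
        except Exception as exc:
            raise StageError("dbc", exc) from exc

    try:
        region_b = tissue_norm.kmeans_region(
            pair.baseline_mask, dilations=config.kmeans_dilations, connectivity=config.connectivity
        )
        region_r = tissue_norm.kmeans_region(
            pair.repeat_mask, dilations=config.kmeans_dilations, connectivity=config.connectivity
        )
        tm_base = tissue_norm.estimate_tissue_means(baseline, region_b, config.connectivity)
        tm_rep = tissue_norm.estimate_tissue_means(repeat, region_r, config.connectivity)
        repeat, a, b = tissue_norm.normalize_pair(baseline, repeat, tm_base, tm_rep)
        tm_rep = tm_rep.rescaled(a, b)
    except Exception as exc:
        raise StageError("normalization", exc) from exc

    try:
        tm_avg = tissue_norm.average_tissue_means(tm_base, tm_rep)
        if config.window_mode == "single":
            windows = (tissue_norm.single_window(tm_avg),)
        else:
            windows = tissue_norm.double_window(tm_avg)
    except Exception as exc:
        raise StageError("window", exc) from exc

    kappa = None
    try:
        region = _build_region(pair.baseline_mask, pair.repeat_mask, config)
        kappa = region.kappa
        empty = region.n_voxels == 0
    except DegenerateRegionError:
        region, empty = None, True
    except Exception as exc:
        raise StageError("region", exc) from exc

    try:
        if empty:
            bsi_mm3, contrib = 0.0, None
            n_voxels = 0
        else:
            if config.window_mode == "single":
                contrib = contribution_map(baseline, repeat, region, windows[0])
            else:
                contrib = contribution_map(
                    baseline, repeat, region, windows[0]
                ) - contribution_map(baseline, repeat, region, windows[1])
            bsi_mm3 = float(contrib.sum())
            n_voxels = region.n_voxels
    except Exception as exc:
        raise StageError("integrate", exc) from exc

    try:
        n_base = int(binarize(pair.baseline_mask, config.binarize_threshold).prob.sum())
        base_vol = n_base * pair.baseline.voxel_volume
        rate = pbvc(
            bsi_mm3,
            pair.baseline_mask,
            pair.interval_years,
            pair.baseline.voxel_volume,
            threshold=config.binarize_threshold,
        )
    except Exception as exc:
        raise StageError("pbvc", exc) from exc

    return BSIResult(
        bsi_mm3=bsi_mm3,
        pbvc_percent_per_year=rate,
        variant=config.variant,
        windows=tuple(windows),
        kappa=kappa,
        region_voxels=n_voxels,
        baseline_volume_mm3=base_vol,
        interval_years=pair.interval_years,
        norm_slope=a,
        norm_intercept=b,
        contributions=contrib if keep_contributions else None,
    )
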