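"""Synthetic registered scan pairs with analytically known volume change.

The phantom is a nested-ellipsoid "brain": a WM core inside a GM shell,
surrounded by CSF, with T1-like contrast (CSF < GM < WM). Atrophy between
time points is simulated by uniformly scaling all semi-axes by
``(1 - atrophy_fraction)^(1/3)``, so the structure's true volume drops by
exactly ``atrophy_fraction`` and the truth stays in closed form
(V = 4/3 * pi * a * b * c).

Partial volume at the boundaries is rasterized analytically: each boundary
voxel's value is its inside-fraction, estimated by 4x4x4 supersampling, so
the probabilistic masks integrate to the analytic volume up to supersampling
error. Optional additive Gaussian noise (both images) and a smooth
multiplicative polynomial bias field (repeat image only, so the effect of
differential bias correction is directly measurable) complete the model.

What this phantom does *not* emulate: cortical folding, sulcal CSF pockets,
anisotropic atrophy, registration/interpolation blur. It exercises every
pipeline stage with a known answer, not anatomical realism.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volumes import ProbMask, ScanPair, VolumeGrid, save_prob_mask, save_volume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "refine_resolution", "write_phantom"]

#: refuse to rasterize grids larger than this many voxels (memory guard)
MAX_VOXELS = 2**27


@dataclass
class PhantomSpec:
    grid_shape: tuple = (96, 96, 96)
    voxel_size: float = 1.0
    csf_intensity: float = 20.0
    gm_intensity: float = 100.0
    wm_intensity: float = 160.0
    outer_semiaxes: tuple = (30.0, 26.0, 22.0)  # mm, GM outer surface
    inner_semiaxes: tuple = (18.0, 15.0, 12.0)  # mm, WM core
    atrophy_fraction: float = 0.02
    interval_years: float = 1.0
    pv_sigma: float = 0.0  # mm, optional extra blur on top of analytic PV
    noise_sd: float = 0.0  # intensity units, additive Gaussian
    bias_amplitude: float = 0.0  # peak deviation of the repeat bias field from 1
    supersample: int = 4
    #: "whole": the mask is the full structure (outer ellipsoid) — the
    #: whole-brain case. "shell": the mask is the GM shell only, bordered by
    #: CSF outside and WM inside — the hippocampus-style two-border case.
    mask_structure: str = "whole"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.atrophy_fraction <= 0.2):
            raise ValidationError("atrophy_fraction must be in [0, 0.2]")
        if not (self.csf_intensity < self.gm_intensity < self.wm_intensity):
            raise ValidationError("intensities must be ordered CSF < GM < WM")
        extent = np.asarray(self.grid_shape) * self.voxel_size
        if np.any(2 * np.asarray(self.outer_semiaxes) >= extent):
            raise ValidationError("structure does not fit inside the grid")
        if np.any(np.asarray(self.inner_semiaxes) >= np.asarray(self.outer_semiaxes)):
            raise ValidationError("inner semi-axes must be smaller than outer")
        if self.mask_structure not in ("whole", "shell"):
            raise ValidationError("mask_structure must be 'whole' or 'shell'")
        if int(np.prod(self.grid_shape)) > MAX_VOXELS:
            raise ValidationError(
                f"grid of {int(np.prod(self.grid_shape))} voxels exceeds the "
                f"{MAX_VOXELS}-voxel cap"
            )


@dataclass
class PhantomTruth:
    true_volume_baseline_mm3: float
    true_volume_repeat_mm3: float
    true_pbvc_percent_per_year: float
    interval_years: float = 1.0

    def to_dict(self) -> dict:
        return {
            "true_volume_baseline_mm3": self.true_volume_baseline_mm3,
            "true_volume_repeat_mm3": self.true_volume_repeat_mm3,
            "true_pbvc_percent_per_year": self.true_pbvc_percent_per_year,
            "interval_years": self.interval_years,
        }


def ellipsoid_volume(semiaxes) -> float:
    a, b, c = semiaxes
    return 4.0 / 3.0 * np.pi * a * b * c


def _inside_fraction(shape, voxel_size: float, center, semiaxes, supersample: int) -> np.ndarray:
    """Per-voxel inside-fraction of an ellipsoid, supersampled at the boundary.

    Voxels whose center is safely inside (outside) get 1 (0); only the
    boundary band is evaluated at supersample^3 subvoxel points.
    """
    semiaxes = np.asarray(semiaxes, dtype=float)
    coords = [
        (np.arange(n) + 0.5) * voxel_size - c for n, c in zip(shape, center)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij", sparse=True)
    r = np.sqrt((xx / semiaxes[0]) ** 2 + (yy / semiaxes[1]) ** 2 + (zz / semiaxes[2]) ** 2)
    # |grad r| <= 1/min(a); band of 2 half-diagonals is conservative
    margin = np.sqrt(3) * voxel_size / semiaxes.min()
    frac = (r < 1.0).astype(np.float64)
    band = np.abs(r - 1.0) <= margin
    if band.any():
        idx = np.argwhere(band)
        s = supersample
        off = ((np.arange(s) + 0.5) / s - 0.5) * voxel_size
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)
        centers = (idx + 0.5) * voxel_size - np.asarray(center)  # (n, 3)
        pts = centers[:, None, :] + offsets[None, :, :]
        g = ((pts / semiaxes) ** 2).sum(axis=2)
        frac[band] = (g < 1.0).mean(axis=1)
    return frac


def _bias_field(shape, amplitude: float) -> np.ndarray:
    """Smooth low-order polynomial multiplicative field, peak deviation = amplitude."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    xn, yn, zn = np.meshgrid(*axes, indexing="ij", sparse=True)
    p = 0.5 * xn + 0.3 * yn + 0.2 * zn**2 + 0.0 * xn * yn
    p = p / np.max(np.abs(p))
    return 1.0 + amplitude * p


def make_phantom(spec: PhantomSpec) -> tuple[ScanPair, PhantomTruth]:
    """Build a registered baseline/repeat pair with known volume change."""
    shape = tuple(int(n) for n in spec.grid_shape)
    vs = float(spec.voxel_size)
    center = tuple(n * vs / 2.0 for n in shape)
    scale = (1.0 - spec.atrophy_fraction) ** (1.0 / 3.0)
    rng = np.random.default_rng(spec.seed)

    def build(sc: float) -> tuple[np.ndarray, np.ndarray]:
        outer = np.asarray(spec.outer_semiaxes) * sc
        inner = np.asarray(spec.inner_semiaxes) * sc
        f_out = _inside_fraction(shape, vs, center, outer, spec.supersample)
        f_in = _inside_fraction(shape, vs, center, inner, spec.supersample)
        img = (
            spec.csf_intensity
            + (spec.gm_intensity - spec.csf_intensity) * f_out
            + (spec.wm_intensity - spec.gm_intensity) * f_in
        )
        mask = f_out if spec.mask_structure == "whole" else f_out - f_in
        return img, mask

    img_b, mask_b = build(1.0)
    if spec.atrophy_fraction == 0.0:
        img_r, mask_r = img_b.copy(), mask_b.copy()
    else:
        img_r, mask_r = build(scale)

    if spec.pv_sigma > 0:
        sig = spec.pv_sigma / vs
        img_b = ndimage.gaussian_filter(img_b, sig)
        img_r = ndimage.gaussian_filter(img_r, sig)
        mask_b = np.clip(ndimage.gaussian_filter(mask_b, sig), 0.0, 1.0)
        mask_r = np.clip(ndimage.gaussian_filter(mask_r, sig), 0.0, 1.0)

    if spec.noise_sd > 0:
        img_b = img_b + rng.normal(0.0, spec.noise_sd, shape)
        img_r = img_r + rng.normal(0.0, spec.noise_sd, shape)

    if spec.bias_amplitude != 0.0:
        img_r = img_r * _bias_field(shape, spec.bias_amplitude)

    voxel_size = np.array([vs, vs, vs])
    base = VolumeGrid(data=img_b, voxel_size=voxel_size)
    rep = VolumeGrid(data=img_r, voxel_size=voxel_size)
    pair = ScanPair(
        baseline=base,
        repeat=rep,
        baseline_mask=ProbMask(prob=mask_b, grid=base),
        repeat_mask=ProbMask(prob=mask_r, grid=rep),
        interval_years=spec.interval_years,
    )
    if spec.mask_structure == "whole":
        v_base = ellipsoid_volume(spec.outer_semiaxes)
    else:
        v_base = ellipsoid_volume(spec.outer_semiaxes) - ellipsoid_volume(spec.inner_semiaxes)
    # uniform scaling of every semi-axis scales either structure volume by s^3
    v_rep = v_base * (1.0 - spec.atrophy_fraction)
    truth = PhantomTruth(
        true_volume_baseline_mm3=v_base,
        true_volume_repeat_mm3=v_rep,
        true_pbvc_percent_per_year=100.0 * spec.atrophy_fraction / spec.interval_years,
        interval_years=spec.interval_years,
    )
    return pair, truth


def refine_resolution(spec: PhantomSpec, factor: int) -> PhantomSpec:
    """The same physical phantom at ``factor``-times finer voxels.

    Analytic truth volumes are grid-free, so they are unchanged; only the
    rasterization gets finer. Raises if the refined grid exceeds the
    memory cap.
    """
    if factor < 1:
        raise ValidationError("factor must be >= 1")
    if factor == 1:
        return spec
    new_shape = tuple(int(n) * factor for n in spec.grid_shape)
    if int(np.prod(new_shape)) > MAX_VOXELS:
        raise ValidationError(
            f"refined grid of {int(np.prod(new_shape))} voxels exceeds the cap"
        )
    return replace(spec, grid_shape=new_shape, voxel_size=spec.voxel_size / factor)


def write_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write baseline/repeat images + masks as NIfTI and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pair, truth = make_phantom(spec)
    paths = {
        "baseline": outdir / "baseline.nii.gz",
        "repeat": outdir / "repeat.nii.gz",
        "baseline_mask": outdir / "baseline_mask.nii.gz",
        "repeat_mask": outdir / "repeat_mask.nii.gz",
        "truth": outdir / "truth.json",
    }
    save_volume(pair.baseline, paths["baseline"])
    save_volume(pair.repeat, paths["repeat"])
    save_prob_mask(pair.baseline_mask, paths["baseline_mask"])
    save_prob_mask(pair.repeat_mask, paths["repeat_mask"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}
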