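"""Domain types for 3D volumes and probabilistic masks, plus NIfTI I/O.

All computation in this package happens on a single voxel grid: the inputs
are assumed to be resampled into a common half-way space already, so a
:class:`VolumeGrid` carries only the data array, the voxel dimensions and
the affine. No resampling or reorientation is performed anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridError, ValidationError

__all__ = [
    "VolumeGrid",
    "ProbMask",
    "ScanPair",
    "load_volume",
    "load_prob_mask",
    "save_volume",
    "save_prob_mask",
    "binarize",
]

#: masks resampled with linear/spline interpolation commonly overshoot [0, 1]
#: by a tiny amount; anything beyond this is treated as a wrong file.
PROB_OVERSHOOT_TOL = 1e-3


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel dimensions (mm) and an affine.

    Attributes
    ----------
    data : ndarray
        3D array of intensities, arbitrary units.
    voxel_size : ndarray
        Three strictly positive voxel edge lengths, mm.
    affine : ndarray
        4x4 voxel-to-world matrix (orientation metadata only; never used to
        resample).
    """

    data: np.ndarray
    voxel_size: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got {self.data.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,):
            raise ValidationError("voxel_size must have exactly 3 components")
        if not np.all(self.voxel_size > 0):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size}")
        n_bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if n_bad:
            raise ValidationError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValidationError("affine must be 4x4")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume D in mm^3 (product of the three voxel sizes)."""
        return float(np.prod(self.voxel_size))

    def same_grid(self, other: "VolumeGrid", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size, rtol=rtol
        )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid sharing this grid's geometry with replaced intensities."""
        return VolumeGrid(data=data, voxel_size=self.voxel_size.copy(), affine=self.affine.copy())


@dataclass
class ProbMask:
    """A field of region-membership probabilities in [0, 1] on a grid."""

    prob: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.prob.shape} does not match grid {self.grid.shape}"
            )
        lo, hi = float(self.prob.min()), float(self.prob.max())
        if lo < -PROB_OVERSHOOT_TOL or hi > 1.0 + PROB_OVERSHOOT_TOL:
            raise ValidationError(
                f"mask values outside [0,1] beyond tolerance: min={lo:.6g}, max={hi:.6g}"
            )
        # tolerated resampling overshoot is clamped silently
        np.clip(self.prob, 0.0, 1.0, out=self.prob)

    @property
    def shape(self) -> tuple:
        return self.prob.shape

    def binary(self) -> np.ndarray:
        """Boolean array of the mask thresholded at 0.5 (ties inside)."""
        return self.prob >= 0.5


@dataclass
class ScanPair:
    """A co-registered baseline/repeat pair with probabilistic masks.

    Both images and both masks must live on one grid (the half-way space);
    ``interval_years`` is the scan interval used for annualization.
    """

    baseline: VolumeGrid
    repeat: VolumeGrid
    baseline_mask: ProbMask
    repeat_mask: ProbMask
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        if self.interval_years <= 0:
            raise ValidationError(f"interval_years must be > 0, got {self.interval_years}")
        for name, g in (("repeat", self.repeat),):
            if not self.baseline.same_grid(g):
                raise GridError(f"{name} image is not on the baseline grid")
        for name, m in (("baseline_mask", self.baseline_mask), ("repeat_mask", self.repeat_mask)):
            if m.shape != self.baseline.shape:
                raise GridError(f"{name} is not on the baseline grid")


def load_volume(path) -> VolumeGrid:
    """Load a NIfTI-1/2 volume (optionally .gz) as a :class:`VolumeGrid`.

    4D files with a singleton trailing dimension are squeezed to 3D; any
    other extra non-singleton dimension is an error.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O error types
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        extra = data.shape[3:]
        if all(s == 1 for s in extra):
            data = data.reshape(data.shape[:3])
        else:
            raise ValidationError(
                f"{path}: {data.ndim}D volume with non-singleton extra dimensions {extra}"
            )
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        data=np.asarray(data, dtype=np.float64),
        voxel_size=np.asarray(zooms, dtype=float),
        affine=np.asarray(img.affine, dtype=float),
    )


def load_prob_mask(path, grid: VolumeGrid) -> ProbMask:
    """Load a probabilistic mask and attach it to ``grid``.

    Values must be genuine probabilities in [0, 1]; tiny resampling
    overshoots (<= 1e-3) are clamped, larger violations raise. Scaled
    integer encodings are rejected rather than guessed at.
    """
    vol = load_volume(path)
    if vol.shape != grid.shape:
        raise GridError(f"mask shape {vol.shape} does not match grid {grid.shape}")
    return ProbMask(prob=vol.data, grid=grid)


def save_volume(grid: VolumeGrid, path) -> None:
    """Write a VolumeGrid as NIfTI-1, preserving dtype of ``grid.data``."""
    img = nib.Nifti1Image(grid.data, grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size))
    nib.save(img, str(path))


def save_prob_mask(mask: ProbMask, path) -> None:
    save_volume(mask.grid.with_data(mask.prob), path)


def binarize(mask: ProbMask, threshold: float = 0.5) -> ProbMask:
    """Threshold a probabilistic mask: 1 where prob >= threshold, else 0.

    A voxel exactly at the threshold counts as inside, so a uniform-0.5
    mask binarized at 0.5 is full.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0,1), got {threshold}")
    return ProbMask(prob=(mask.prob >= threshold).astype(float), grid=mask.grid)
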