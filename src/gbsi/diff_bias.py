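"""Symmetric differential bias correction (DBC).

Even after per-scan inhomogeneity correction, the baseline and repeat images
of a pair carry different residual smooth bias fields. Because the boundary
shift integral subtracts clipped intensities voxelwise, any smooth intensity
difference between time points masquerades as boundary shift. DBC estimates
the differential field as the median-filtered log-intensity difference
inside a brain mask and splits the correction equally between the two
images (multiplicative model):

    d = log(baseline) - log(repeat)
    baseline' = baseline * exp(-median_filter(d)/2)
    repeat'   = repeat   * exp(+median_filter(d)/2)

so the per-voxel geometric mean is preserved and neither time point is
privileged. The median filter runs over a cubic neighborhood of half-width
``kernel_radius`` (default 5, i.e. an 11^3 cube) and *excludes* voxels
outside the mask from every neighborhood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DomainError, ValidationError
from .volumes import ProbMask, VolumeGrid

__all__ = ["DbcParams", "kernel_footprint", "masked_median_filter", "differential_bias_correct"]

#: histogram resolution of the masked median; quantization error of the
#: estimated log-bias is at most (range of d in mask) / N_MEDIAN_BINS.
N_MEDIAN_BINS = 512


@dataclass
class DbcParams:
    """DBC configuration: kernel radius (voxels) and estimation mask."""

    mask: ProbMask
    kernel_radius: int = 5

    def __post_init__(self) -> None:
        if self.kernel_radius < 1:
            raise ValidationError(f"kernel_radius must be >= 1, got {self.kernel_radius}")


def kernel_footprint(kernel_radius: int) -> np.ndarray:
    """Cubic (Chebyshev-ball) footprint of size (2r+1)^3."""
    if kernel_radius < 1:
        raise ValidationError(f"kernel_radius must be >= 1, got {kernel_radius}")
    side = 2 * kernel_radius + 1
    return np.ones((side, side, side), dtype=bool)


def _box_sum(arr: np.ndarray, r: int) -> np.ndarray:
    """Sum over the cubic neighborhood of half-width r, via 3 running cumsums."""
    out = arr.astype(np.float64)
    for ax in range(3):
        c = np.cumsum(out, axis=ax)
        pad_shape = list(c.shape)
        pad_shape[ax] = r + 1
        zeros = np.zeros(pad_shape, dtype=c.dtype)
        upper = np.concatenate([c, np.repeat(c.take([-1], axis=ax), r, axis=ax)], axis=ax)
        upper = upper.take(range(r, r + c.shape[ax]), axis=ax)
        lower = np.concatenate([zeros, c], axis=ax)
        lower = lower.take(range(c.shape[ax]), axis=ax)
        out = upper - lower
    return out


def masked_median_filter(d: np.ndarray, mask: np.ndarray, radius: int) -> np.ndarray:
    """Median of ``d`` over each voxel's (2r+1)^3 cube, in-mask voxels only.

    Computed by a streaming histogram median: values are binned over the
    in-mask range and per-bin box sums locate, for each voxel, the bins
    where the cumulative in-mask neighbor count crosses the two central
    ranks; the result is the mean of those bins' centers (the true median,
    so the filter stays antisymmetric under ``d -> -d``). Quantization
    error is at most one bin width ((max-min)/512 by default). Voxels
    outside the mask get 0.

    This is the behavior scipy's median filter cannot provide (it has no
    notion of invalid neighbors), hence the dedicated implementation.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise DegenerateInputError("DBC mask is empty")
    vals = d[mask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros_like(d, dtype=np.float64)
    if hi - lo < 1e-12:  # constant field is its own median
        out[mask] = lo
        return out

    # crop to the mask bounding box padded by the radius, for speed
    idx = np.argwhere(mask)
    lo_i = np.maximum(idx.min(axis=0) - radius, 0)
    hi_i = np.minimum(idx.max(axis=0) + radius + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo_i, hi_i))
    m = mask[sl]
    dv = d[sl]

    width = (hi - lo) / N_MEDIAN_BINS
    bins = np.clip(((dv - lo) / width).astype(np.int32), 0, N_MEDIAN_BINS - 1)
    counts = _box_sum(m, radius)
    # true median: average of the two central ranks (equal for odd counts),
    # which keeps the filter antisymmetric under d -> -d
    need_lo = np.floor((counts + 1.0) / 2.0)
    need_hi = np.floor(counts / 2.0) + 1.0

    cum = np.zeros_like(counts)
    result_lo = np.full(dv.shape, np.nan)
    result_hi = np.full(dv.shape, np.nan)
    open_lo = m.copy()
    open_hi = m.copy()
    for k in range(N_MEDIAN_BINS):
        cum += _box_sum(m & (bins == k), radius)
        center = lo + (k + 0.5) * width
        hit = open_lo & (cum >= need_lo)
        if hit.any():
            result_lo[hit] = center
            open_lo &= ~hit
        hit = open_hi & (cum >= need_hi)
        if hit.any():
            result_hi[hit] = center
            open_hi &= ~hit
        if not open_hi.any():
            break
    out[sl][m] = 0.5 * (result_lo[m] + result_hi[m])
    return out


def differential_bias_correct(
    baseline: VolumeGrid, repeat: VolumeGrid, params: DbcParams
) -> tuple[VolumeGrid, VolumeGrid]:
    """Apply symmetric DBC; returns the corrected (baseline, repeat) pair.

    Voxels outside the estimation mask are returned unchanged. Raises
    :class:`DomainError` if any in-mask intensity is <= 0 (the log-domain
    model requires positive intensities).
    """
    if not baseline.same_grid(repeat):
        raise DomainError("baseline and repeat are not on one grid")
    mask = params.mask.prob >= 0.5
    if not mask.any():
        raise DegenerateInputError("DBC mask is empty")
    n_bad = int(np.count_nonzero((baseline.data[mask] <= 0) | (repeat.data[mask] <= 0)))
    if n_bad:
        raise DomainError(
            f"{n_bad} in-mask voxel(s) have non-positive intensity; log-domain DBC undefined"
        )
    d = np.zeros(baseline.shape, dtype=np.float64)
    d[mask] = np.log(baseline.data[mask]) - np.log(repeat.data[mask])
    d_smooth = masked_median_filter(d, mask, params.kernel_radius)
    half = np.where(mask, d_smooth / 2.0, 0.0)
    base_c = baseline.data * np.exp(-half)
    rep_c = repeat.data * np.exp(half)
    return baseline.with_data(base_c), repeat.with_data(rep_c)
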