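"""Tissue-intensity estimation, inter-scan normalization and window selection.

The boundary shift integral is only meaningful if the two time points share
one intensity scale and if the integration is restricted to the intensity
band that actually separates the tissues flanking the boundary. This module
provides the three ingredients:

* a deterministic 1-D k-means (k = 3) that estimates CSF/GM/WM mean
  intensities inside the (dilated) brain mask,
* a linear-regression normalization mapping the repeat image onto the
  baseline intensity scale through the paired tissue means, and
* automatic intensity clipping-window selection: ``[csf_mean + csf_sd,
  gm_mean - gm_sd]`` for the tissue–CSF border, with a second
  ``[gm_mean + gm_sd, wm_mean - wm_sd]`` window for small GM structures
  (hippocampus) that also border white matter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    FitError,
    ValidationError,
    WindowCollapseError,
)
from .volumes import ProbMask, VolumeGrid, binarize

__all__ = [
    "TissueMeans",
    "IntensityWindow",
    "kmeans_region",
    "estimate_tissue_means",
    "normalize_pair",
    "average_tissue_means",
    "single_window",
    "double_window",
]

KMEANS_MAX_ITER = 300


def _structuring_element(connectivity: int = 6) -> np.ndarray:
    """3D structuring element: 6-connected (faces) or 26-connected (cube)."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


@dataclass
class TissueMeans:
    """Per-tissue intensity statistics (CSF < GM < WM ordering enforced)."""

    csf_mean: float
    csf_std: float
    gm_mean: float
    gm_std: float
    wm_mean: float
    wm_std: float
    interior_mean: float

    def __post_init__(self) -> None:
        if not (self.csf_mean < self.gm_mean < self.wm_mean):
            raise ValidationError(
                "tissue means must be ordered CSF < GM < WM, got "
                f"{self.csf_mean:.4g}, {self.gm_mean:.4g}, {self.wm_mean:.4g}"
            )
        for s in (self.csf_std, self.gm_std, self.wm_std):
            if s < 0:
                raise ValidationError("tissue SDs must be >= 0")

    def as_points(self) -> np.ndarray:
        """The four mean intensities used by the normalization regression."""
        return np.array([self.csf_mean, self.gm_mean, self.wm_mean, self.interior_mean])

    def rescaled(self, a: float, b: float) -> "TissueMeans":
        """Statistics after the affine intensity map ``I -> a*I + b``."""
        return TissueMeans(
            csf_mean=a * self.csf_mean + b,
            csf_std=abs(a) * self.csf_std,
            gm_mean=a * self.gm_mean + b,
            gm_std=abs(a) * self.gm_std,
            wm_mean=a * self.wm_mean + b,
            wm_std=abs(a) * self.wm_std,
            interior_mean=a * self.interior_mean + b,
        )


@dataclass(frozen=True)
class IntensityWindow:
    """Clipping bounds [low, high] for one tissue boundary."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise WindowCollapseError(
                f"intensity window collapsed: low={self.low:.4g} >= high={self.high:.4g}"
            )

    @property
    def width(self) -> float:
        return self.high - self.low


def kmeans_region(mask: ProbMask, dilations: int = 3, connectivity: int = 6) -> ProbMask:
    """The region tissue statistics are estimated in.

    The probabilistic mask is binarized at 0.5 and dilated ``dilations``
    times (default 3) with a face-adjacent structuring element so that the
    region includes some CSF outside the structure.
    """
    if dilations < 0:
        raise ValidationError("dilations must be >= 0")
    binary = binarize(mask, 0.5).prob.astype(bool)
    if not binary.any():
        raise DegenerateInputError("binarized mask is empty; cannot build k-means region")
    if dilations:
        binary = ndimage.binary_dilation(
            binary, structure=_structuring_element(connectivity), iterations=dilations
        )
    return ProbMask(prob=binary.astype(float), grid=mask.grid)


def _kmeans_1d(values: np.ndarray, k: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic Lloyd k-means on a 1-D sample.

    Centers start at the 10th/50th/90th percentiles; iteration stops when no
    assignment changes. Returns (sorted centers, labels relative to sorted
    order).
    """
    centers = np.percentile(values, np.linspace(10, 90, k))
    labels = np.zeros(len(values), dtype=np.int64)
    for _ in range(KMEANS_MAX_ITER):
        d = np.abs(values[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1)
        changed = int(np.count_nonzero(new_labels != labels))
        labels = new_labels
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = values[sel].mean()
        if changed == 0 and _ > 0:
            break
    else:
        raise ConvergenceError(
            f"k-means did not converge in {KMEANS_MAX_ITER} iterations "
            f"(last iteration changed {changed} assignments)"
        )
    order = np.argsort(centers)
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return centers[order], remap[labels]


def estimate_tissue_means(
    image: VolumeGrid, region: ProbMask, connectivity: int = 6
) -> TissueMeans:
    """Estimate CSF/GM/WM means and SDs by k-means (k = 3) inside ``region``.

    Clusters are labeled CSF/GM/WM in ascending order of cluster mean, so the
    labeling never depends on the internal cluster order. The interior mean
    is the mean intensity inside the once-eroded 0.5-binarized region, i.e.
    with the partial-volume rim stripped off.
    """
    sel = region.prob >= 0.5
    values = image.data[sel]
    if values.size < 9:
        raise DegenerateInputError(f"region has only {values.size} voxels; need >= 9")
    if np.unique(values).size < 3:
        raise DegenerateInputError(
            "fewer than 3 distinct intensity values in region; k-means (k=3) is degenerate"
        )
    centers, labels = _kmeans_1d(values, k=3)
    stats = []
    for j in range(3):
        v = values[labels == j]
        stats.append((float(v.mean()), float(v.std())))
    eroded = ndimage.binary_erosion(sel, structure=_structuring_element(connectivity))
    if eroded.any():
        interior = float(image.data[eroded].mean())
    else:
        # mask too thin to erode: fall back to the un-eroded region mean
        interior = float(values.mean())
    return TissueMeans(
        csf_mean=stats[0][0],
        csf_std=stats[0][1],
        gm_mean=stats[1][0],
        gm_std=stats[1][1],
        wm_mean=stats[2][0],
        wm_std=stats[2][1],
        interior_mean=interior,
    )


def normalize_pair(
    baseline: VolumeGrid,
    repeat: VolumeGrid,
    tm_base: TissueMeans,
    tm_rep: TissueMeans,
) -> tuple[VolumeGrid, float, float]:
    """Map the repeat image onto the baseline intensity scale.

    An ordinary least-squares line is fitted through the four paired points
    (repeat tissue mean -> baseline tissue mean) for CSF, GM, WM and the
    interior region; the repeat image is transformed voxelwise as
    ``a*I + b``. The baseline is untouched by convention.

    Returns
    -------
    (normalized_repeat, a, b)
    """
    x = tm_rep.as_points()
    y = tm_base.as_points()
    if np.ptp(x) == 0:
        raise FitError("repeat tissue means are all equal; normalization fit is degenerate")
    a, b = np.polyfit(x, y, 1)
    return repeat.with_data(a * repeat.data + b), float(a), float(b)


def average_tissue_means(tm1: TissueMeans, tm2: TissueMeans) -> TissueMeans:
    """Fieldwise average of the two time points' tissue statistics."""
    return TissueMeans(
        **{
            f: (getattr(tm1, f) + getattr(tm2, f)) / 2.0
            for f in (
                "csf_mean",
                "csf_std",
                "gm_mean",
                "gm_std",
                "wm_mean",
                "wm_std",
                "interior_mean",
            )
        }
    )


def single_window(tm: TissueMeans) -> IntensityWindow:
    """CSF–GM clipping window: low = CSF mean + SD, high = GM mean − SD.

    ``tm`` should be the average of the two time points' tissue statistics.
    Raises :class:`WindowCollapseError` when the tissue distributions
    overlap so much that low >= high.
    """
    try:
        return IntensityWindow(low=tm.csf_mean + tm.csf_std, high=tm.gm_mean - tm.gm_std)
    except WindowCollapseError as exc:
        raise WindowCollapseError(f"CSF-GM {exc}") from None


def double_window(tm: TissueMeans) -> tuple[IntensityWindow, IntensityWindow]:
    """CSF–GM and GM–WM clipping windows for two-border (hippocampal) BSI.

    The second window applies the same selection rule to the GM/WM pair:
    low = GM mean + SD, high = WM mean − SD.
    """
    w1 = single_window(tm)
    try:
        w2 = IntensityWindow(low=tm.gm_mean + tm.gm_std, high=tm.wm_mean - tm.wm_std)
    except WindowCollapseError as exc:
        raise WindowCollapseError(f"GM-WM {exc}") from None
    return w1, w2
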