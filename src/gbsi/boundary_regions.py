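"""Boundary-shift region construction: binary XOR, probabilistic XOR, fuzzy.

The region R is the voxelwise weight field the integral is taken over.
Variants:

``binary_xor``
    The classic construction: dilate the union and erode the intersection of
    the 0.5-binarized masks, R = 1 on their set difference.

``pxor_gbsi``
    Probabilistic XOR of the raw probability fields,
    ``pXOR = A*(1-B) + (1-A)*B - A*(1-B)*(1-A)*B``, rescaled by an adaptive
    gain factor kappa (the mean of the nonzero pXOR values): voxels below
    kappa get weight pXOR/kappa, voxels at or above kappa get weight 1. With
    kappa = 1 and binary masks this reverts exactly to the binary XOR with
    no dilation/erosion.

``pbsi_1`` / ``pbsi_gamma``
    Fuzzy-set construction: threshold the fuzzy union (max) at zeta and the
    fuzzy intersection (min) at eta, dilate/erode, and weight the resulting
    binary XOR shell by max(gamma, (A+B)/2). gamma = 1 gives uniform weights
    (pBSI_1); gamma = 0.5 gives weights in [0.5, 1] (pBSI_gamma).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateRegionError, GridError, ValidationError
from .tissue_norm import _structuring_element
from .volumes import ProbMask, binarize

__all__ = [
    "BoundaryRegion",
    "PbsiParams",
    "pxor",
    "adaptive_kappa",
    "gbsi_region",
    "binary_xor_region",
    "pbsi_region",
]


@dataclass
class PbsiParams:
    """Fuzzy-region parameters: eta/zeta thresholds, morphology counts, gamma."""

    eta: float = 0.95
    zeta: float = 0.90
    n_erode: int = 0
    n_dilate: int = 1
    gamma: float = 1.0
    #: how the two time points' probabilities combine before max(gamma, .):
    #: "mean" (default) or "max"
    combine: str = "mean"

    def __post_init__(self) -> None:
        for name, v in (("eta", self.eta), ("zeta", self.zeta), ("gamma", self.gamma)):
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0,1], got {v}")
        if self.n_erode < 0 or self.n_dilate < 0:
            raise ValidationError("n_erode and n_dilate must be >= 0")
        if self.combine not in ("mean", "max"):
            raise ValidationError(f"combine must be 'mean' or 'max', got {self.combine!r}")


@dataclass
class BoundaryRegion:
    """Voxelwise region weights R in [0,1] plus the variant that built them."""

    weights: np.ndarray
    variant: str
    kappa: Optional[float] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.min() < 0 or w.max() > 1:
            raise ValidationError("region weights must lie in [0, 1]")
        self.weights = w
        if (self.variant == "pxor_gbsi") != (self.kappa is not None):
            raise ValidationError("kappa must be present iff variant is pxor_gbsi")

    @property
    def n_voxels(self) -> int:
        """Count of strictly positive weights."""
        return int(np.count_nonzero(self.weights > 0))


def _check_same_grid(A: ProbMask, B: ProbMask) -> None:
    if A.shape != B.shape or not np.allclose(A.grid.voxel_size, B.grid.voxel_size):
        raise GridError("masks are not on one grid")


def pxor(A: ProbMask, B: ProbMask) -> np.ndarray:
    """Probabilistic exclusive OR of two probability fields.

    ``pXOR = A*Bc + Ac*B - (A*Bc)*(Ac*B)`` with ``Xc = 1 - X``; approaches 1
    where the two time points' segmentations disagree strongly, and is 0
    exactly where both probabilities are 0 or both are 1.
    """
    _check_same_grid(A, B)
    a, b = A.prob, B.prob
    p = a * (1.0 - b)
    q = (1.0 - a) * b
    return p + q - p * q


def adaptive_kappa(pxor_field: np.ndarray) -> float:
    """Gain factor kappa: the mean of all strictly positive pXOR voxels."""
    nz = pxor_field[pxor_field > 0]
    if nz.size == 0:
        raise DegenerateRegionError("pXOR is identically zero (identical masks)")
    return float(nz.mean())


def gbsi_region(
    A: ProbMask, B: ProbMask, kappa_override: Optional[float] = None
) -> BoundaryRegion:
    """Adaptive probabilistic-XOR region.

    Weights are ``pXOR/kappa`` where ``pXOR < kappa`` and 1 otherwise (note
    the strict inequality: voxels exactly at kappa get weight 1). kappa is
    the adaptive mean of the nonzero pXOR values unless overridden.
    """
    px = pxor(A, B)
    kappa = float(kappa_override) if kappa_override is not None else adaptive_kappa(px)
    if not (0.0 < kappa <= 1.0):
        raise ValidationError(f"kappa must be in (0,1], got {kappa}")
    weights = np.where(px < kappa, px / kappa, 1.0)
    return BoundaryRegion(weights=weights, variant="pxor_gbsi", kappa=kappa)


def binary_xor_region(
    A: ProbMask,
    B: ProbMask,
    n_dilate: int = 1,
    n_erode: int = 1,
    threshold: float = 0.5,
    connectivity: int = 6,
) -> BoundaryRegion:
    """Classic binary XOR shell: dilated union minus eroded intersection."""
    _check_same_grid(A, B)
    if n_dilate < 0 or n_erode < 0:
        raise ValidationError("n_dilate and n_erode must be >= 0")
    se = _structuring_element(connectivity)
    a = binarize(A, threshold).prob.astype(bool)
    b = binarize(B, threshold).prob.astype(bool)
    union = a | b
    inter = a & b
    if n_dilate:
        union = ndimage.binary_dilation(union, structure=se, iterations=n_dilate)
    if n_erode:
        inter = ndimage.binary_erosion(inter, structure=se, iterations=n_erode)
    weights = (union & ~inter).astype(float)
    return BoundaryRegion(
        weights=weights,
        variant="binary_xor",
        params={"n_dilate": n_dilate, "n_erode": n_erode, "connectivity": connectivity},
    )


def pbsi_region(A: ProbMask, B: ProbMask, params: PbsiParams, connectivity: int = 6) -> BoundaryRegion:
    """Fuzzy-logic XOR region weighted by max(gamma, combined probability).

    U = dilate(max(A,B) >= zeta, n_dilate); N = erode(min(A,B) >= eta,
    n_erode); on the shell X = U & ~N the weight is
    ``max(gamma, (A+B)/2)`` (or max(gamma, max(A,B)) with combine="max");
    zero elsewhere.
    """
    _check_same_grid(A, B)
    se = _structuring_element(connectivity)
    union = np.maximum(A.prob, B.prob) >= params.zeta
    inter = np.minimum(A.prob, B.prob) >= params.eta
    if params.n_dilate:
        union = ndimage.binary_dilation(union, structure=se, iterations=params.n_dilate)
    if params.n_erode:
        inter = ndimage.binary_erosion(inter, structure=se, iterations=params.n_erode)
    shell = union & ~inter
    if params.combine == "mean":
        p = (A.prob + B.prob) / 2.0
    else:
        p = np.maximum(A.prob, B.prob)
    weights = np.where(shell, np.maximum(params.gamma, p), 0.0)
    variant = "pbsi_1" if params.gamma == 1.0 else "pbsi_gamma"
    return BoundaryRegion(weights=weights, variant=variant, params=vars(params).copy())
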