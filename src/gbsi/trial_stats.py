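"""Clinical-trial sample-size estimation from annualized PBVC distributions.

For a two-arm trial powered at 80% with a two-sided 5% significance level,
the per-arm sample size to detect a treatment effect Delta on a normally
distributed outcome with common SD sigma is

    n = (0.841 + 1.96)^2 * 2 * sigma^2 / Delta^2

where 0.841 and 1.96 are the standard-normal quantiles for 80% power and
the 5% two-sided test; they are kept as literal constants so the arithmetic
matches the convention used in atrophy-trial power calculations exactly.

The treatment effect is a fractional reduction (default 25%) of disease
progression: Delta = reduction * patient-group mean PBVC, or — when
"controlling for normal aging" — reduction * (patient mean − control mean).
In both cases sigma is the patient-group SD: the trial arms are patients;
controls only shift the effect size.

Bias-corrected (BC) bootstrap confidence intervals resample subjects with
replacement within each group and recompute the sample size per replicate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "POWER_CONSTANT",
    "GroupStats",
    "SampleSizeResult",
    "sample_size",
    "effect_size",
    "bootstrap_ci",
    "sample_size_table",
    "read_pbvc_table",
]

#: (z_{0.80 power} + z_{0.975})^2 = (0.841 + 1.96)^2
POWER_CONSTANT = (0.841 + 1.96) ** 2


@dataclass
class GroupStats:
    """Per-group PBVC summary; per-subject values optional (for bootstrap)."""

    label: str
    n: int
    mean_pbvc: float
    sd_pbvc: float
    values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.sd_pbvc < 0:
            raise ValidationError("sd_pbvc must be >= 0")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.n != len(self.values):
                raise ValidationError("n does not match len(values)")
            if self.n < 2:
                raise ValidationError("need >= 2 subjects when values are present")
            if not math.isclose(self.values.mean(), self.mean_pbvc, rel_tol=1e-6, abs_tol=1e-6):
                raise ValidationError("mean_pbvc does not match values")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        return cls(label=label, n=len(v), mean_pbvc=float(v.mean()),
                   sd_pbvc=float(v.std(ddof=1)), values=v)


@dataclass
class SampleSizeResult:
    n_per_arm: int
    raw: float
    delta: float
    sigma: float
    controlled_for_aging: bool
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def sample_size(sigma: float, delta: float) -> tuple[float, int]:
    """Per-arm sample size; returns (unrounded, nearest-integer) pair."""
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    if delta == 0:
        raise ValidationError("effect size delta is 0; sample size undefined")
    raw = POWER_CONSTANT * 2.0 * sigma**2 / delta**2
    return raw, int(round(raw))


def effect_size(
    ad: GroupStats, controls: Optional[GroupStats] = None, reduction: float = 0.25
) -> tuple[float, float]:
    """Treatment effect Delta and outcome SD sigma for the trial.

    Without controls Delta = reduction * patient mean; with controls
    (controlling for normal aging) Delta = reduction * (patient mean −
    control mean). sigma is always the patient-group SD.
    """
    if not (0.0 < reduction < 1.0):
        raise ValidationError(f"reduction must be in (0,1), got {reduction}")
    if controls is None:
        return reduction * ad.mean_pbvc, ad.sd_pbvc
    excess = ad.mean_pbvc - controls.mean_pbvc
    if excess <= 0:
        raise ValidationError(
            f"patient mean ({ad.mean_pbvc}) must exceed control mean "
            f"({controls.mean_pbvc}) for a positive effect"
        )
    return reduction * excess, ad.sd_pbvc


def estimate_sample_size(
    ad: GroupStats, controls: Optional[GroupStats] = None, reduction: float = 0.25
) -> SampleSizeResult:
    delta, sigma = effect_size(ad, controls, reduction)
    raw, n = sample_size(sigma, delta)
    return SampleSizeResult(
        n_per_arm=n, raw=raw, delta=delta, sigma=sigma,
        controlled_for_aging=controls is not None,
    )


def _replicate_sample_size(ad_vals: np.ndarray, ctrl_vals: Optional[np.ndarray],
                           reduction: float) -> float:
    sigma = ad_vals.std(ddof=1)
    if ctrl_vals is None:
        delta = reduction * ad_vals.mean()
    else:
        delta = reduction * (ad_vals.mean() - ctrl_vals.mean())
    if delta <= 0:
        return math.inf  # degenerate resample: effect vanished
    # zero-variance resample: any effect is detectable with no subjects
    return POWER_CONSTANT * 2.0 * sigma**2 / delta**2


def bootstrap_ci(
    ad_values: Sequence[float],
    control_values: Optional[Sequence[float]] = None,
    reduction: float = 0.25,
    n_boot: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """95% bias-corrected bootstrap CI for the per-arm sample size.

    Subjects are resampled with replacement within each group; the sample
    size is recomputed per replicate; the BC interval uses
    z0 = Phi^{-1}(fraction of replicates below the point estimate) and the
    percentiles Phi(2*z0 -/+ 1.96). Replicates where the resampled effect
    is non-positive count as +inf.
    """
    ad = np.asarray(ad_values, dtype=float)
    if len(ad) < 2:
        raise ValidationError("need >= 2 patient values")
    ctrl = None if control_values is None else np.asarray(control_values, dtype=float)
    if ctrl is not None and len(ctrl) < 2:
        raise ValidationError("need >= 2 control values")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    point = _replicate_sample_size(ad, ctrl, reduction)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        a = ad[rng.integers(0, len(ad), len(ad))]
        c = None if ctrl is None else ctrl[rng.integers(0, len(ctrl), len(ctrl))]
        reps[i] = _replicate_sample_size(a, c, reduction)
    if np.all(reps == reps[0]):
        return point, point  # no resampling variance: interval collapses
    frac_below = np.mean(reps < point)
    frac_below = min(max(frac_below, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = norm.ppf(frac_below)
    alpha_lo = norm.cdf(2 * z0 - 1.96)
    alpha_hi = norm.cdf(2 * z0 + 1.96)
    finite = np.isfinite(reps)
    if finite.all():
        lo, hi = np.quantile(reps, [alpha_lo, alpha_hi])
    else:
        # +inf replicates sort above every finite one; quantiles still defined
        s = np.sort(reps)
        lo = s[min(int(alpha_lo * n_boot), n_boot - 1)]
        hi = s[min(int(alpha_hi * n_boot), n_boot - 1)]
    return float(lo), float(hi)


def sample_size_table(
    stats_by_method: Sequence[tuple[str, GroupStats, Optional[GroupStats]]],
    reduction: float = 0.25,
    with_ci: bool = False,
    n_boot: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-method sample sizes, with and without controlling for aging.

    Each entry of ``stats_by_method`` is (method label, patient group,
    control group or None). Rows: "alone" (patient rates alone) and
    "controlling" (for normal aging); a missing control group marks the
    controlling cell unavailable. CIs require per-subject values.
    """
    if not stats_by_method:
        raise ValidationError("need at least one method")
    columns = {}
    for label, ad, controls in stats_by_method:
        cells = {}
        for row, ctrl in (("alone", None), ("controlling", controls)):
            if row == "controlling" and controls is None:
                cells[row] = "n/a"
                continue
            res = estimate_sample_size(ad, ctrl, reduction)
            cell = f"{res.n_per_arm}"
            if with_ci and ad.values is not None and (ctrl is None or ctrl.values is not None):
                lo, hi = bootstrap_ci(
                    ad.values,
                    None if ctrl is None else ctrl.values,
                    reduction=reduction, n_boot=n_boot, seed=seed,
                )
                cell += f" ({lo:.0f}-{hi:.0f})"
            cells[row] = cell
        columns[label] = cells
    return pd.DataFrame(columns)


def read_pbvc_table(path) -> dict[str, GroupStats]:
    """Read per-subject PBVC from delimited text (subject, group, pbvc[, interval]).

    Returns one GroupStats per group label, built from the values.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "group" not in cols or "pbvc" not in cols:
        raise ValidationError("table must have 'group' and 'pbvc' columns")
    out = {}
    for g, sub in df.groupby(cols["group"]):
        out[str(g)] = GroupStats.from_values(str(g), sub[cols["pbvc"]].to_numpy())
    return out
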