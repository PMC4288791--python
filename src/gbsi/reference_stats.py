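"""Published ADNI cohort PBVC group statistics, bundled as fixtures.

Mean (SD) of annualized percentage volume change, per method and field
strength, from a published ADNI-1 analysis (baseline vs 12-month scans;
1.5 T: 195 controls / 133 AD patients; 3 T: 39 controls / 24 AD). These
printed summary statistics are *inputs* to the sample-size machinery —
the cohort images themselves are not redistributable — and drive both the
worked examples and the trial-statistics self-checks.
"""
from __future__ import annotations

from .trial_stats import GroupStats

__all__ = ["WHOLE_BRAIN_15T", "WHOLE_BRAIN_3T", "HIPPOCAMPUS_15T", "HIPPOCAMPUS_3T",
           "group_stats", "METHODS_WHOLE_BRAIN", "METHODS_HIPPOCAMPUS"]

METHODS_WHOLE_BRAIN = ("manual-KN-BSI", "STEPS-KN-BSI", "pBSI1", "pBSIg", "gBSI")
METHODS_HIPPOCAMPUS = ("STEPS-KN-BSI", "pBSI1", "pBSIg", "gBSI")

# method -> {"controls": (n, mean, sd), "ad": (n, mean, sd)}
WHOLE_BRAIN_15T = {
    "manual-KN-BSI": {"controls": (195, 0.56, 0.60), "ad": (133, 1.40, 0.77)},
    "STEPS-KN-BSI": {"controls": (195, 0.55, 0.56), "ad": (133, 1.35, 0.72)},
    "pBSI1": {"controls": (195, 0.49, 0.51), "ad": (133, 1.25, 0.65)},
    "pBSIg": {"controls": (195, 0.34, 0.36), "ad": (133, 0.88, 0.48)},
    "gBSI": {"controls": (195, 0.53, 0.56), "ad": (133, 1.34, 0.69)},
}

WHOLE_BRAIN_3T = {
    "manual-KN-BSI": {"controls": (39, 0.45, 0.79), "ad": (24, 1.26, 0.71)},
    "STEPS-KN-BSI": {"controls": (39, 0.40, 0.73), "ad": (24, 1.22, 0.70)},
    "pBSI1": {"controls": (39, 0.39, 0.75), "ad": (24, 1.24, 0.72)},
    "pBSIg": {"controls": (39, 0.22, 0.51), "ad": (24, 0.81, 0.47)},
    "gBSI": {"controls": (39, 0.39, 0.71), "ad": (24, 1.20, 0.69)},
}

HIPPOCAMPUS_15T = {
    "STEPS-KN-BSI": {"controls": (195, 1.12, 2.20), "ad": (133, 4.88, 3.23)},
    "pBSI1": {"controls": (195, 0.69, 1.62), "ad": (133, 2.91, 2.23)},
    "pBSIg": {"controls": (195, 0.40, 1.25), "ad": (133, 1.63, 1.72)},
    "gBSI": {"controls": (195, 0.87, 1.86), "ad": (133, 3.90, 2.54)},
}

HIPPOCAMPUS_3T = {
    "STEPS-KN-BSI": {"controls": (39, 0.35, 2.27), "ad": (24, 3.35, 3.08)},
    "pBSI1": {"controls": (39, 0.37, 2.30), "ad": (24, 3.34, 3.10)},
    "pBSIg": {"controls": (39, 0.21, 1.53), "ad": (24, 1.74, 2.35)},
    "gBSI": {"controls": (39, 0.15, 1.86), "ad": (24, 2.61, 2.46)},
}


def group_stats(table: dict, method: str, group: str) -> GroupStats:
    """A :class:`GroupStats` for one method/group cell of a bundled table."""
    n, mean, sd = table[method][group]
    return GroupStats(label=f"{method}:{group}", n=n, mean_pbvc=mean, sd_pbvc=sd)
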