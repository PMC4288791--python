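"""Pipeline configuration: one flat record of every tunable parameter.

Defaults are the standard fixed parameter set of the pipeline (DBC kernel
radius 5, three k-means mask dilations, one XOR dilation/erosion, fuzzy
thresholds eta=0.95 / zeta=0.90 with n_e=0 / n_d=1, 0.5 binarization,
6-connected morphology). Configs round-trip through a flat TOML file so a
run is reproducible from its logged parameter set alone.
"""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import ValidationError

VARIANTS = ("pxor_gbsi", "binary_xor", "pbsi_1", "pbsi_gamma")
WINDOW_MODES = ("single", "double")


@dataclass
class PipelineConfig:
    variant: str = "pxor_gbsi"
    window_mode: str = "single"
    dbc: bool = True
    dbc_kernel_radius: int = 5
    kmeans_dilations: int = 3
    xor_dilate: int = 1
    xor_erode: int = 1
    pbsi_eta: float = 0.95
    pbsi_zeta: float = 0.90
    pbsi_n_erode: int = 0
    pbsi_n_dilate: int = 1
    pbsi_gamma: float = 1.0
    pbsi_combine: str = "mean"
    binarize_threshold: float = 0.5
    connectivity: int = 6
    kappa_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.window_mode not in WINDOW_MODES:
            raise ValidationError(f"window_mode must be one of {WINDOW_MODES}")
        if self.variant == "pbsi_gamma" and self.pbsi_gamma == 1.0:
            self.pbsi_gamma = 0.5
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValidationError("binarize_threshold must be in (0,1)")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        """Write as a flat TOML file (None-valued fields omitted)."""
        lines = []
        for k, v in self.to_dict().items():
            if v is None:
                continue
            if isinstance(v, bool):
                lines.append(f"{k} = {'true' if v else 'false'}")
            elif isinstance(v, str):
                lines.append(f'{k} = "{v}"')
            else:
                lines.append(f"{k} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
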