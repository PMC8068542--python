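"""Run configuration shared across the pipeline.

Defaults reproduce the method's stated choices: a quantization ladder of
[128, 64, 16, 8] bins, 64x64 segmentation windows, the rho label bins
0.5 / 0.7 / 0.9, an LSTM with 100 hidden cells and a look-back of 3, and
a retina-field threshold of 100 on the raw RGB channel sum.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("fundustex")

#: Quantization ladder applied to every segment before GLCM construction.
DEFAULT_LEVELS: tuple[int, ...] = (128, 64, 16, 8)

#: The four canonical GLCM offset angles, in degrees.
DEFAULT_ANGLES: tuple[int, ...] = (0, 45, 90, 135)


class ConfigError(ValueError):
    """Raised when a RunConfig fails validation."""


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults."""

    # texture encoding
    levels: tuple[int, ...] = DEFAULT_LEVELS
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = DEFAULT_ANGLES
    glcm_symmetric: bool = True
    energy_sqrt: bool = False  # text-variant energy = sqrt(ASM)

    # segmentation / labeling
    window: int = 64
    rho_gate: float = 0.5           # segments with rho <= gate are non-candidate
    rho_bins: tuple[float, float, float] = (0.5, 0.7, 0.9)
    roi_coverage: float = 0.05      # mask fraction for a window to count as ROI

    # LSTM
    hidden: int = 100
    look_back: int = 3
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 32

    # pixel classification
    polarity: str = "bright"        # "bright" (exudates) or "dark" (vessels)
    gamma_c: float = 1.0
    background_threshold: int = 100

    # preprocessing
    apply_clahe: bool = True
    clahe_clip: float = 0.03
    clahe_tiles: tuple[int, int] = (8, 8)

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.levels or any(l < 2 for l in self.levels):
            raise ConfigError("quantization levels must be non-empty, each >= 2")
        if self.glcm_distance < 1:
            raise ConfigError("glcm_distance must be >= 1")
        if any(a not in (0, 45, 90, 135) for a in self.glcm_angles):
            raise ConfigError("glcm_angles restricted to {0, 45, 90, 135}")
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        lo, mid, hi = self.rho_bins
        if not (-1.0 <= lo < mid < hi <= 1.0):
            raise ConfigError("rho_bins must be strictly increasing within [-1, 1]")
        if not 0.0 <= self.roi_coverage <= 1.0:
            raise ConfigError("roi_coverage must be a fraction in [0, 1]")
        if self.hidden < 1 or self.look_back < 1:
            raise ConfigError("hidden and look_back must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.polarity not in ("bright", "dark"):
            raise ConfigError("polarity must be 'bright' or 'dark'")
        if self.gamma_c <= 0:
            raise ConfigError("gamma_c must be positive")
        if self.clahe_clip <= 0:
            raise ConfigError("clahe_clip must be positive")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("levels", "glcm_angles", "rho_bins", "clahe_tiles"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("levels", "glcm_angles", "rho_bins", "clahe_tiles"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
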