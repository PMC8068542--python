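"""Local-extrema gray-level quantization.

A gray image (or segment) is rescaled by a chosen extrema range
[i_min, i_max] and mapped onto L_Q integer bins with a ceiling operator:

    I_int(m, n) = ceil( (I(m, n) - i_min) / (i_max - i_min) * L_Q )

with results clamped into [1, L_Q]. Computing the same image at several
quantization levels (the ladder, default [128, 64, 16, 8]) exposes texture
at multiple resolutions; choosing the extrema locally to a region stretches
that region's gray range over the full bin ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_LEVELS

logger = logging.getLogger("fundustex")


class DegenerateRangeError(ValueError):
    """Raised when i_min == i_max so the rescaling is undefined."""


@dataclass(frozen=True)
class ExtremaRange:
    """Intensity range [i_min, i_max] used to rescale before binning."""

    i_min: int
    i_max: int

    def __post_init__(self):
        if self.i_min > self.i_max:
            raise ValueError(f"i_min {self.i_min} exceeds i_max {self.i_max}")

    @classmethod
    def of(cls, img: np.ndarray) -> "ExtremaRange":
        img = np.asarray(img)
        return cls(int(img.min()), int(img.max()))


@dataclass
class QuantizedImage:
    """Bin-index image with values in [1, level]."""

    pixels: np.ndarray
    level: int
    extrema: ExtremaRange


@dataclass
class QuantizedStack:
    """One image quantized at every level of the ladder, shape-aligned."""

    images: list[QuantizedImage]
    source_shape: tuple[int, int]

    @property
    def levels(self) -> list[int]:
        return [q.level for q in self.images]

    def __iter__(self):
        return iter(self.images)


def quantize(img: np.ndarray, level: int, extrema: ExtremaRange) -> QuantizedImage:
    """Quantize ``img`` into ``level`` bins over the given extrema range.

    Pixels at or below i_min map to bin 1, pixels at or above i_max to bin
    ``level``; a degenerate range (i_min == i_max) raises
    :class:`DegenerateRangeError`.
    """
    if level < 2:
        raise ValueError("quantization level must be >= 2")
    if extrema.i_min == extrema.i_max:
        raise DegenerateRangeError(
            f"degenerate extrema range [{extrema.i_min}, {extrema.i_max}]"
        )
    img = np.asarray(img, dtype=np.float64)
    span = float(extrema.i_max - extrema.i_min)
    intermediate = np.ceil((img - extrema.i_min) / span * level)
    binned = np.clip(intermediate, 1, level).astype(np.int64)
    return QuantizedImage(binned, level, extrema)


def quantize_stack(img: np.ndarray, levels=DEFAULT_LEVELS,
                   extrema: ExtremaRange | None = None) -> QuantizedStack:
    """Quantize ``img`` at every level of the ladder.

    ``extrema`` defaults to the min/max of ``img`` itself — global extrema
    when called on a whole image, local extrema when called on a segment.
    A constant region (degenerate range) maps every pixel to bin 1 at every
    level, with a warning, so batch pipelines stay total.
    """
    if not levels or any(l < 2 for l in levels):
        raise ValueError("levels must be non-empty, each >= 2")
    img = np.asarray(img)
    if extrema is None:
        extrema = ExtremaRange.of(img)
    images = []
    for level in levels:
        try:
            images.append(quantize(img, level, extrema))
        except DegenerateRangeError:
            logger.warning(
                "degenerate extrema range at value %d: mapping all pixels to bin 1",
                extrema.i_min,
            )
            images.append(QuantizedImage(np.ones(img.shape, dtype=np.int64),
                                         level, extrema))
    return QuantizedStack(images, tuple(img.shape))
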