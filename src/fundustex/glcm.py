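"""Gray-level co-occurrence matrices.

C[i, j] counts ordered pixel pairs (p, p + offset) whose values are the
gray levels i and j (levels run 1..L). Offsets are parameterized by a
distance d and one of the four canonical angles; summing the four angles
gives the rotation-invariant form, and the symmetric variant also counts
each pair in the reverse direction, making the matrix equal to its
transpose. Out-of-bounds neighbors are skipped, so the total count equals
the number of in-bounds pairs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quantize import QuantizedImage

# angle -> (row step, col step) per unit distance; 0 deg points along +col,
# angles increase counter-clockwise (45 deg is up-right).
ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class GlcmDomainError(ValueError):
    """Raised when image values fall outside [1, L]."""


class DegenerateGlcmError(ValueError):
    """Raised when no in-bounds pixel pair exists for the given offsets."""


@dataclass(frozen=True)
class Offset:
    """A co-occurrence offset (d, theta) with theta in {0, 45, 90, 135}."""

    d: int = 1
    theta: int = 0

    def __post_init__(self):
        if self.d < 1:
            raise ValueError("offset distance must be a positive integer")
        if self.theta not in ANGLE_STEPS:
            raise ValueError("offset angle must be one of {0, 45, 90, 135}")

    @property
    def step(self) -> tuple[int, int]:
        dr, dc = ANGLE_STEPS[self.theta]
        return dr * self.d, dc * self.d


def default_offsets(d: int = 1, angles=(0, 45, 90, 135)) -> list[Offset]:
    return [Offset(d, a) for a in angles]


@dataclass
class Glcm:
    """Co-occurrence counts and, once normalized, the probability matrix."""

    counts: np.ndarray
    level: int
    offsets: list[Offset] = field(default_factory=list)
    symmetric: bool = False
    normalized: np.ndarray | None = None

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())


def _as_levels(img) -> tuple[np.ndarray, int | None]:
    if isinstance(img, QuantizedImage):
        return np.asarray(img.pixels), img.level
    return np.asarray(img), None


def glcm_counts(img, offsets=None, symmetric: bool = True,
                level: int | None = None,
                valid: np.ndarray | None = None) -> Glcm:
    """Accumulate co-occurrence counts over the given offsets.

    ``img`` is a QuantizedImage or any small integer image with values in
    [1, L]; L defaults to the quantization level or the image maximum.
    With ``symmetric`` both directions of every offset are counted.
    ``valid``, when given, is a boolean mask of the same shape: pairs with
    either pixel invalid are skipped (used to keep non-retina background
    out of a window's texture statistics).
    """
    pixels, inherent_level = _as_levels(img)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("glcm_counts expects a non-empty 2-D integer image")
    if offsets is None:
        offsets = default_offsets()
    if not offsets:
        raise ValueError("at least one offset is required")
    L = level if level is not None else inherent_level
    if L is None:
        L = int(pixels.max())
    low = pixels < 1
    high = pixels > L
    if low.any() or high.any():
        r, c = np.argwhere(low | high)[0]
        raise GlcmDomainError(
            f"pixel value {pixels[r, c]} at ({r}, {c}) outside [1, {L}]"
        )
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != pixels.shape:
            raise ValueError("valid mask must match the image shape")

    counts = np.zeros((L, L), dtype=np.int64)
    M, N = pixels.shape
    for off in offsets:
        dr, dc = off.step
        r0, r1 = max(0, -dr), M - max(0, dr)
        c0, c1 = max(0, -dc), N - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        a = pixels[r0:r1, c0:c1]
        b = pixels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if valid is not None:
            keep = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
            a, b = a[keep], b[keep]
        a = a.ravel() - 1
        b = b.ravel() - 1
        np.add.at(counts, (a, b), 1)
        if symmetric:
            np.add.at(counts, (b, a), 1)
    return Glcm(counts, L, list(offsets), symmetric)


def normalize(g: Glcm) -> Glcm:
    """Divide counts by the total pair count to get a probability matrix."""
    total = g.total_pairs
    if total == 0:
        raise DegenerateGlcmError(
            "no in-bounds pixel pairs: image smaller than every offset"
        )
    return Glcm(g.counts, g.level, g.offsets, g.symmetric,
                normalized=g.counts.astype(np.float64) / total)
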