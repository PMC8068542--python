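"""Haralick texture descriptors from a normalized GLCM.

Five descriptors are used: homogeneity, entropy, energy (angular second
moment), correlation, and contrast. A segment is encoded by computing
them on its GLCM at each level of the quantization ladder (with extrema
local to the segment) and concatenating in ladder order — 4 levels x 5
descriptors = a 20-component feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_LEVELS
from .glcm import default_offsets, glcm_counts, normalize
from .quantize import ExtremaRange, quantize_stack

logger = logging.getLogger("fundustex")

NORMALIZATION_TOL = 1e-9

#: Descriptor order within one level's block of the feature vector.
FEATURE_NAMES = ("homogeneity", "entropy", "energy", "correlation", "contrast")


@dataclass(frozen=True)
class HaralickVector:
    """The five descriptors for one quantization level."""

    homogeneity: float
    entropy: float
    energy: float
    correlation: float
    contrast: float
    level: int | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.homogeneity, self.entropy, self.energy,
                         self.correlation, self.contrast])


def haralick_features(p, level: int | None = None,
                      energy_sqrt: bool = False) -> HaralickVector:
    """Compute the five descriptors from a normalized GLCM ``p``.

    ``p`` is a Glcm with its ``normalized`` matrix set, or the probability
    matrix itself. Gray-level indices run 1..L. Conventions: 0*ln(0) = 0 in
    the entropy sum, and correlation is defined as 0 when either marginal
    standard deviation vanishes (point-mass matrices).
    """
    if hasattr(p, "normalized"):
        if p.normalized is None:
            raise ValueError("GLCM must be normalized first (call normalize)")
        p = p.normalized
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("normalized GLCM must be a square matrix")
    if (p < 0).any() or abs(p.sum() - 1.0) > NORMALIZATION_TOL:
        raise ValueError("input is not a normalized GLCM (entries must be >= 0 "
                         "and sum to 1)")
    L = p.shape[0]
    i = np.arange(1, L + 1, dtype=np.float64)[:, None]
    j = np.arange(1, L + 1, dtype=np.float64)[None, :]
    diff = i - j

    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    asm = float((p ** 2).sum())
    energy = float(np.sqrt(asm)) if energy_sqrt else asm
    contrast = float((diff ** 2 * p).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i.ravel() * px).sum())
    mu_y = float((j.ravel() * py).sum())
    var_x = float(((i.ravel() - mu_x) ** 2 * px).sum())
    var_y = float(((j.ravel() - mu_y) ** 2 * py).sum())
    if var_x <= 0.0 or var_y <= 0.0:
        logger.debug("zero marginal variance: correlation defined as 0")
        correlation = 0.0
    else:
        correlation = float(
            ((i - mu_x) * (j - mu_y) * p).sum() / np.sqrt(var_x * var_y)
        )
    return HaralickVector(homogeneity, entropy, energy, correlation, contrast,
                          level=level)


#: Descriptor block of a point-mass (single-bin) GLCM.
POINT_MASS_BLOCK = (1.0, 0.0, 1.0, 0.0, 0.0)


def encode_segment(segment: np.ndarray, levels=DEFAULT_LEVELS,
                   distance: int = 1, angles=(0, 45, 90, 135),
                   symmetric: bool = True,
                   energy_sqrt: bool = False,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Encode one gray window as the multi-resolution feature vector.

    The window is quantized at every ladder level with extrema local to
    the window itself, a normalized symmetric GLCM is built per level, and
    the five descriptors are concatenated in ladder order. A constant
    window quantizes to all-ones at every level and yields the point-mass
    descriptor block [1, 0, 1, 0, 0] per level.

    ``valid`` restricts the window to its retina-field pixels: extrema are
    taken over valid pixels only and co-occurrence pairs touching invalid
    pixels are skipped, so windows straddling the camera aperture are
    described by their in-field texture. A window with no (or all-equal)
    valid pixels degrades to the point-mass encoding.
    """
    segment = np.asarray(segment)
    if segment.ndim != 2 or segment.size == 0:
        raise ValueError("segment must be a non-empty 2-D gray window")
    offsets = default_offsets(distance, angles)
    extrema = None
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != segment.shape:
            raise ValueError("valid mask must match the segment shape")
        if valid.all():
            valid = None
        else:
            vals = segment[valid]
            extrema = (ExtremaRange(int(vals.min()), int(vals.max()))
                       if vals.size else ExtremaRange(0, 0))
    stack = quantize_stack(segment, levels, extrema=extrema)
    features = []
    for q in stack:
        g = glcm_counts(q, offsets, symmetric=symmetric, valid=valid)
        if g.total_pairs == 0:
            features.append(np.array(POINT_MASS_BLOCK))
            continue
        g = normalize(g)
        features.append(haralick_features(g.normalized, level=q.level,
                                          energy_sqrt=energy_sqrt).as_array())
    return np.concatenate(features)


def encode_segment_config(segment: np.ndarray, config,
                          valid: np.ndarray | None = None) -> np.ndarray:
    """encode_segment with parameters taken from a RunConfig."""
    return encode_segment(segment, levels=config.levels,
                          distance=config.glcm_distance,
                          angles=config.glcm_angles,
                          symmetric=config.glcm_symmetric,
                          energy_sqrt=config.energy_sqrt,
                          valid=valid)
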