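"""Window segmentation, the benchmark ROI feature, and rho labeling.

The image is tiled into non-overlapping 64x64 windows (zero-padded on the
bottom/right so an integer number of windows fits). Every window is
encoded as a 20-component texture feature vector. Ground-truth-positive
training windows are averaged into a benchmark ROI feature F_ROI, and a
window's symptom score rho is the Pearson correlation between its feature
vector and F_ROI, mapped to an ordinal label:

    rho < 0.5          -> none
    0.5 <= rho < 0.7   -> mild
    0.7 <= rho < 0.9   -> strong
    0.9 <= rho <= 1    -> very_strong
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .haralick import encode_segment_config

logger = logging.getLogger("fundustex")


class SegmentLabel(Enum):
    NONE = "none"
    MILD = "mild"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


@dataclass
class SegmentGrid:
    """Raster-ordered tiling of an image into square windows."""

    window: int
    image_shape: tuple[int, int]     # original, before padding
    padded: np.ndarray               # zero-padded image, tiled exactly
    grid_shape: tuple[int, int]      # (segment rows, segment cols)
    field: np.ndarray | None = None  # padded bool retina-field mask, or None
    features: np.ndarray | None = None   # (n_segments, 20)
    rho: np.ndarray | None = None        # (n_segments,)
    labels: list[SegmentLabel] | None = None

    @property
    def n_segments(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def padding(self) -> tuple[int, int]:
        return (self.padded.shape[0] - self.image_shape[0],
                self.padded.shape[1] - self.image_shape[1])

    def bounds(self, index: int) -> tuple[int, int, int, int]:
        """Half-open pixel bounds (r0, r1, c0, c1) of segment ``index``."""
        rows, cols = self.grid_shape
        r, c = divmod(index, cols)
        w = self.window
        return r * w, (r + 1) * w, c * w, (c + 1) * w

    def segment(self, index: int) -> np.ndarray:
        r0, r1, c0, c1 = self.bounds(index)
        return self.padded[r0:r1, c0:c1]

    def segment_valid(self, index: int) -> np.ndarray | None:
        if self.field is None:
            return None
        r0, r1, c0, c1 = self.bounds(index)
        return self.field[r0:r1, c0:c1]

    def segment_windows(self):
        for idx in range(self.n_segments):
            yield self.segment(idx)


@dataclass
class RoiBenchmark:
    """Mean feature vector of the ground-truth ROI training windows."""

    vector: np.ndarray
    n_sources: int


def tile(img: np.ndarray, window: int = 64,
         field_mask: np.ndarray | None = None) -> SegmentGrid:
    """Tile ``img`` into window x window segments, zero-padding bottom/right.

    ``field_mask`` (optional, image-shaped, nonzero = retina field) is
    padded alongside; windows then expose per-segment validity so the
    camera-aperture background can be kept out of texture statistics.
    Padding pixels are always invalid when a field mask is present.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("tile expects a 2-D gray image")
    M, N = img.shape
    rows = -(-M // window)
    cols = -(-N // window)
    padded = np.zeros((rows * window, cols * window), dtype=img.dtype)
    padded[:M, :N] = img
    field = None
    if field_mask is not None:
        field_mask = np.asarray(field_mask)
        if field_mask.shape != (M, N):
            raise ValueError("field_mask shape must match the image")
        field = np.zeros(padded.shape, dtype=bool)
        field[:M, :N] = field_mask > 0
    return SegmentGrid(window=window, image_shape=(M, N), padded=padded,
                       grid_shape=(rows, cols), field=field)


def reassemble(grid: SegmentGrid) -> np.ndarray:
    """Drop the padding: recover the original image from the tiling."""
    M, N = grid.image_shape
    return grid.padded[:M, :N].copy()


def encode_grid(grid: SegmentGrid, config) -> SegmentGrid:
    """Fill ``grid.features`` with the 20-vector of every segment (raster order)."""
    feats = [encode_segment_config(grid.segment(i), config,
                                   valid=grid.segment_valid(i))
             for i in range(grid.n_segments)]
    grid.features = np.asarray(feats)
    return grid


@dataclass
class FeatureScaler:
    """Per-component standardization fitted on a training feature population.

    The 20 descriptors live on wildly different scales (contrast at 128
    bins is orders of magnitude above homogeneity), so the Pearson score
    between raw vectors is dominated by the large-magnitude components.
    Features are therefore z-scored with training-population statistics
    before any correlation is computed.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, features) -> "FeatureScaler":
        F = np.asarray(features, dtype=np.float64)
        if F.ndim != 2 or F.shape[0] < 1:
            raise ValueError("fit expects a (n_samples, n_features) matrix")
        std = F.std(axis=0)
        std[std == 0] = 1.0
        return cls(F.mean(axis=0), std)

    def transform(self, features) -> np.ndarray:
        return (np.asarray(features, dtype=np.float64) - self.mean) / self.std


def build_benchmark(roi_features) -> RoiBenchmark:
    """Elementwise mean of the N training-ROI feature vectors."""
    roi_features = [np.asarray(f, dtype=np.float64) for f in roi_features]
    if not roi_features:
        raise ValueError("cannot build a benchmark from an empty ROI list")
    stacked = np.vstack(roi_features)
    return RoiBenchmark(stacked.mean(axis=0), stacked.shape[0])


def collect_roi_features(grid: SegmentGrid, mask: np.ndarray, config):
    """Feature vectors of windows whose ground-truth coverage exceeds the
    configured fraction (these are the ROI training windows)."""
    mask = np.asarray(mask)
    if mask.shape != grid.image_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {grid.image_shape}"
        )
    if grid.features is None:
        encode_grid(grid, config)
    padded_mask = np.zeros(grid.padded.shape, dtype=np.uint8)
    padded_mask[:mask.shape[0], :mask.shape[1]] = mask > 0
    out = []
    area = grid.window ** 2
    for idx in range(grid.n_segments):
        r0, r1, c0, c1 = grid.bounds(idx)
        if padded_mask[r0:r1, c0:c1].sum() / area > config.roi_coverage:
            out.append(grid.features[idx])
    return out


def correlation_rho(x, y) -> float:
    """Pearson correlation across the components of two feature vectors.

    Defined as 0 (with a debug log) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("feature vectors must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).mean())
    sy = np.sqrt((yc ** 2).mean())
    if sx == 0.0 or sy == 0.0:
        logger.debug("zero-variance feature vector: rho defined as 0")
        return 0.0
    rho = float((xc * yc).mean() / (sx * sy))
    # guard against rounding outside [-1, 1]
    return float(np.clip(rho, -1.0, 1.0))


def label_from_rho(rho: float,
                   bins: tuple[float, float, float] = (0.5, 0.7, 0.9)) -> SegmentLabel:
    """Map a correlation score to its ordinal symptom label.

    The bins partition [-1, 1]; the printed gap [0.89, 0.9) is closed by
    extending *strong* up to (but excluding) 0.9.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho {rho} outside [-1, 1]")
    lo, mid, hi = bins
    if rho < lo:
        return SegmentLabel.NONE
    if rho < mid:
        return SegmentLabel.MILD
    if rho < hi:
        return SegmentLabel.STRONG
    return SegmentLabel.VERY_STRONG


def score_grid_correlation(grid: SegmentGrid, benchmark,
                           scaler: FeatureScaler | None = None) -> np.ndarray:
    """Raw rho of every segment against the benchmark, in raster order.

    With a scaler, segment features are standardized before correlation
    (the benchmark is expected to live in the standardized space already).
    """
    if grid.features is None:
        raise ValueError("grid has no features; call encode_grid first")
    vec = benchmark.vector if isinstance(benchmark, RoiBenchmark) else np.asarray(benchmark)
    feats = scaler.transform(grid.features) if scaler is not None else grid.features
    return np.array([correlation_rho(f, vec) for f in feats])
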