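"""Pixel-level lesion detection inside high-rho segments.

For every segment whose predicted symptom score rho exceeds 0.5, each of
its four quantized versions is contrast-enhanced with a power-law (gamma)
transform whose exponent is 1 - rho, binarized with Otsu's global
threshold, and the four binary masks are intersected — a pixel is a
candidate only if it separates from background at every quantization
resolution. Segments with rho <= 0.5 are non-candidate wholesale.

The gamma transform is applied to the quantized bin values themselves
(x in 1..L), x -> c * x^(1-rho), rescaled onto [0, 255]: as rho -> 1 the
spacing converges to a logarithmic compression that progressively
stretches the low-bin end. Because the symptom of interest may live at
either end of the gray range, a polarity flag decides which end is
stretched: "dark" (vessels) enhances the low bins directly, "bright"
(exudates) reverses the bin order first; either way the output image
shows the structure bright, so Otsu's upper class is the candidate class.

The vessel pipeline runs this chain on the green channel after zeroing
the outside-aperture background (RGB channel sum <= 100) and with dark
polarity. When a retina-field mask is available,
non-field pixels are excluded from Otsu's histogram and from the final
mask, so the aperture rim cannot capture the threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np

from .image_io import clahe, green_channel
from .quantize import ExtremaRange, QuantizedImage, quantize_stack
from .segments import (FeatureScaler, RoiBenchmark, SegmentGrid, encode_grid,
                       label_from_rho, score_grid_correlation, tile)

logger = logging.getLogger("fundustex")


@dataclass
class DetectionResult:
    """Candidate mask in source coordinates plus per-segment scores."""

    mask: np.ndarray                 # 0/1, original image shape
    rho: np.ndarray                  # per segment, raster order
    labels: list
    grid: SegmentGrid


@dataclass
class BackgroundMask:
    """Retina field (1) vs outside-aperture background (0)."""

    mask: np.ndarray
    threshold: int


class CorrelationScorer:
    """Direct rho provider: segment-feature correlation against a benchmark.

    Interchangeable with a trained LstmRegressor wherever a per-segment
    score is needed.
    """

    def __init__(self, benchmark, scaler: FeatureScaler | None = None):
        self.benchmark = (benchmark.vector
                          if isinstance(benchmark, RoiBenchmark) else
                          np.asarray(benchmark, dtype=np.float64))
        self.scaler = scaler

    def score_grid(self, grid: SegmentGrid) -> np.ndarray:
        return score_grid_correlation(grid, self.benchmark, self.scaler)


def gamma_transform(q: QuantizedImage, rho: float, c: float = 1.0,
                    polarity: str = "bright") -> np.ndarray:
    """Power-law enhancement of a quantized segment with exponent 1 - rho.

    The bin values x (1..L; reversed first for bright polarity so the
    structure-bearing end is stretched) are mapped through c * x**(1-rho)
    and the attainable range [c, c*L^(1-rho)] is rescaled to [0, 255],
    output inverted so the structure of interest is bright. rho = 1 gives
    the constant (all-zero after rescale) image; rho below 0.5 is outside
    the candidate regime and raises.
    """
    if not 0.5 <= rho <= 1.0:
        raise ValueError(f"gamma_transform requires rho in [0.5, 1], got {rho}")
    if c <= 0:
        raise ValueError("gamma constant c must be positive")
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    x = np.asarray(q.pixels, dtype=np.float64)
    L = q.level
    if polarity == "bright":
        x = (L + 1) - x
    exponent = 1.0 - rho
    lo, hi = c * 1.0, c * L ** exponent
    if hi <= lo:  # rho == 1 or L == 1: no contrast left
        return np.zeros(x.shape, dtype=np.uint8)
    y = (c * np.power(x, exponent) - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(255.0 - y), 0, 255).astype(np.uint8)


def otsu_value(img: np.ndarray, exclude: np.ndarray | None = None) -> int | None:
    """Otsu's global threshold maximizing between-class variance.

    Returns the smallest maximizing threshold t (classes: <= t vs > t), or
    None for a constant image, which has no separable classes. ``exclude``
    drops pixels from the histogram.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("otsu on empty image")
    vals = img if exclude is None else img[~np.asarray(exclude, dtype=bool)]
    if vals.size == 0:
        return None
    hist = np.bincount(vals.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        return None
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                       # pixels with value <= t
    s0 = np.cumsum(hist * levels)
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(256)
    mu0 = np.where(w0 > 0, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (s0[-1] - s0) / np.where(w1 > 0, w1, 1), 0.0)
    between[valid] = w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
    return int(np.argmax(between))


def otsu_threshold(img: np.ndarray,
                   exclude: np.ndarray | None = None) -> np.ndarray:
    """Binarize with Otsu's threshold: pixels strictly above it map to 1.

    A constant image yields an all-zero mask (logged); excluded pixels are
    never candidates."""
    t = otsu_value(img, exclude)
    if t is None:
        logger.warning("otsu on a constant image: returning an all-zero mask")
        return np.zeros(np.asarray(img).shape, dtype=np.uint8)
    mask = (np.asarray(img) > t).astype(np.uint8)
    if exclude is not None:
        mask[np.asarray(exclude, dtype=bool)] = 0
    return mask


def intersect_candidates(masks) -> np.ndarray:
    """Logical AND across a list of same-shape binary masks."""
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("intersect_candidates requires at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all masks must share the same shape")
    out = np.ones(shape, dtype=bool)
    for m in masks:
        out &= m > 0
    return out.astype(np.uint8)


def _segment_candidates(segment: np.ndarray, rho: float, config,
                        valid: np.ndarray | None = None) -> np.ndarray:
    """Quantize -> gamma -> Otsu per level, then intersect."""
    extrema = None
    if valid is not None:
        vals = segment[valid]
        extrema = (ExtremaRange(int(vals.min()), int(vals.max()))
                   if vals.size else ExtremaRange(0, 0))
    stack = quantize_stack(segment, config.levels, extrema=extrema)
    exclude = None if valid is None or valid.all() else ~valid
    level_masks = []
    for q in stack:
        transformed = gamma_transform(q, rho, config.gamma_c, config.polarity)
        level_masks.append(otsu_threshold(transformed, exclude))
    return intersect_candidates(level_masks)


def detect_exudates(img: np.ndarray, model, config,
                    field_mask: np.ndarray | None = None,
                    grid: SegmentGrid | None = None) -> DetectionResult:
    """Full candidate-pixel detection on a gray (green-channel) image.

    ``model`` is any per-segment rho provider (a trained LstmRegressor or
    a CorrelationScorer). Segment scoring reads the texture of ``img`` as
    given; the pixel-classification stage binarizes the CLAHE-enhanced
    image (when ``config.apply_clahe``), where the extra local contrast
    sharpens the lesion boundary. Only segments with rho > 0.5 are
    processed; everything else is non-candidate, and the zero padding
    added for tiling is stripped from the returned mask. ``field_mask``
    (optional) marks the retina field; non-field pixels are excluded from
    texture encoding, thresholding and the final mask.
    """
    img = np.asarray(img)
    if grid is None:
        grid = tile(img, config.window, field_mask=field_mask)
    if grid.features is None:
        encode_grid(grid, config)
    rho = np.asarray(model.score_grid(grid), dtype=np.float64)
    rho = np.clip(rho, -1.0, 1.0)
    labels = [label_from_rho(r, config.rho_bins) for r in rho]
    grid.rho = rho
    grid.labels = labels

    if config.apply_clahe:
        enhanced = clahe(img, config.clahe_clip, config.clahe_tiles)
        pixel_grid = tile(enhanced, config.window, field_mask=field_mask)
    else:
        pixel_grid = grid
    mask = np.zeros(grid.padded.shape, dtype=np.uint8)
    for idx in range(grid.n_segments):
        if rho[idx] <= config.rho_gate:
            continue
        r0, r1, c0, c1 = grid.bounds(idx)
        mask[r0:r1, c0:c1] = _segment_candidates(
            pixel_grid.segment(idx), rho[idx], config,
            valid=pixel_grid.segment_valid(idx))
    if grid.field is not None:
        mask &= grid.field.astype(np.uint8)
    M, N = grid.image_shape
    return DetectionResult(mask[:M, :N], rho, labels, grid)


def estimate_background(rgb: np.ndarray, threshold: int = 100) -> BackgroundMask:
    """Retina-field mask: RGB channel sum strictly above the threshold."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError("estimate_background expects an (M, N, 3) RGB image")
    channel_sum = rgb[:, :, :3].astype(np.int64).sum(axis=2)
    return BackgroundMask((channel_sum > threshold).astype(np.uint8), threshold)


def segment_vessels(rgb: np.ndarray, model, config) -> DetectionResult:
    """Vessel segmentation: exudate pipeline with background removal and
    dark polarity on the green channel."""
    bg = estimate_background(rgb, config.background_threshold)
    gray = green_channel(rgb)
    gray = (gray.astype(np.int64) * bg.mask).astype(np.uint8)
    vessel_config = config.replace(polarity="dark")
    result = detect_exudates(gray, model, vessel_config, field_mask=bg.mask)
    result.mask = (result.mask & bg.mask).astype(np.uint8)
    return result


def write_rho_csv(path, result: DetectionResult) -> None:
    """Per-segment (row, col, rho, label) table."""
    rows_n, cols_n = result.grid.grid_shape
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_row", "segment_col", "rho", "label"])
        for idx in range(result.grid.n_segments):
            r, c = divmod(idx, cols_n)
            writer.writerow([r, c, f"{result.rho[idx]:.6f}",
                             result.labels[idx].value])
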