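"""Seeded generator of fundus-like test images with exact ground truth.

Real fundus photographs show a bright circular retina field (the camera
aperture) on a dark background, a dark branching vessel tree, and — in
diabetic retinopathy — small bright hard-exudate blobs. The generator
emulates exactly those ingredients: an aperture disc with a gentle radial
intensity falloff, random-walk vessel curves darker than the field,
Gaussian-profile exudate blobs brighter than the field, and additive
Gaussian pixel noise. Ground-truth masks record the exact pre-noise
geometry of the painted structures, mirroring expert-marked templates.
Generation is pure given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .image_io import green_channel
from .lstm import build_sequences
from .segments import (build_benchmark, collect_roi_features, correlation_rho,
                       encode_grid, label_from_rho, tile)

logger = logging.getLogger("fundustex")


class PlacementError(RuntimeError):
    """Raised when requested blobs cannot be placed without overlap."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic fundus image."""

    size: tuple[int, int] = (256, 256)
    aperture_fraction: float = 0.45   # aperture radius / min(size)
    background: int = 110             # retina-field intensity at center
    outside: int = 5                  # intensity outside the aperture
    vessel_count: int = 6
    vessel_width: tuple[int, int] = (2, 4)
    vessel_depth: int = 40            # vessels are background - depth
    exudate_count: int = 5
    exudate_radius: tuple[int, int] = (4, 10)
    exudate_lift: int = 70            # peak brightness above local field
    noise_std: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if min(self.vessel_count, self.exudate_count) < 0:
            raise ValueError("structure counts must be >= 0")
        if not 0 < self.aperture_fraction <= 0.5:
            raise ValueError("aperture_fraction must be in (0, 0.5]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


def _disc(shape, center, radius):
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _walk_vessel(rng, start, direction, aperture, width):
    """Random-walk curve of stamped discs; stops on leaving the aperture."""
    mask = np.zeros(aperture.shape, dtype=bool)
    pos = np.array(start, dtype=np.float64)
    ang = direction
    half = max(1.0, width / 2.0)
    for _ in range(400):
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) \
                or not aperture[r, c]:
            break
        mask |= _disc(mask.shape, (r, c), half)
        ang += rng.normal(0.0, 0.22)
        pos += 2.0 * np.array([np.sin(ang), np.cos(ang)])
    return mask & aperture


def make_fundus(spec: SyntheticSpec):
    """Generate (RGB image, vessel mask, exudate mask) from the spec."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    center = (H / 2.0, W / 2.0)
    radius = spec.aperture_fraction * min(H, W)
    aperture = _disc((H, W), center, radius)

    rr, cc = np.ogrid[:H, :W]
    rdist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    img = np.full((H, W), float(spec.outside))
    falloff = spec.background - 20.0 * (rdist / max(radius, 1.0)) ** 2
    img[aperture] = falloff[aperture]

    vessel_mask = np.zeros((H, W), dtype=bool)
    for _ in range(spec.vessel_count):
        ang0 = rng.uniform(0, 2 * np.pi)
        start = (center[0] + rng.uniform(-0.15, 0.15) * radius,
                 center[1] + rng.uniform(-0.15, 0.15) * radius)
        width = rng.integers(spec.vessel_width[0], spec.vessel_width[1] + 1)
        vessel_mask |= _walk_vessel(rng, start, ang0, aperture, width)
    img[vessel_mask] -= spec.vessel_depth

    exudate_mask = np.zeros((H, W), dtype=bool)
    r_lo, r_hi = spec.exudate_radius
    for _ in range(spec.exudate_count):
        for _attempt in range(60):
            er = rng.uniform(center[0] - 0.75 * radius, center[0] + 0.75 * radius)
            ec = rng.uniform(center[1] - 0.75 * radius, center[1] + 0.75 * radius)
            rad = int(rng.integers(r_lo, r_hi + 1))
            if (er - center[0]) ** 2 + (ec - center[1]) ** 2 > (0.8 * radius - rad) ** 2:
                continue
            blob = _disc((H, W), (er, ec), rad)
            near = _disc((H, W), (er, ec), rad + 3)
            if (near & (vessel_mask | exudate_mask)).any():
                continue
            sigma = rad / 1.5
            d2 = (rr - er) ** 2 + (cc - ec) ** 2
            profile = spec.exudate_lift * np.exp(-d2 / (2.0 * sigma ** 2))
            img[blob] += profile[blob]
            exudate_mask |= blob
            break
        else:
            raise PlacementError(
                "could not place an exudate blob without overlap; "
                "reduce exudate_count or radius"
            )

    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    gray = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rgb = np.zeros((H, W, 3), dtype=np.uint8)
    rgb[:, :, 0] = np.clip(0.95 * gray.astype(np.float64) + 10, 0, 255).astype(np.uint8)
    rgb[:, :, 1] = gray
    rgb[:, :, 2] = np.clip(0.35 * gray.astype(np.float64), 0, 255).astype(np.uint8)
    return rgb, vessel_mask.astype(np.uint8), exudate_mask.astype(np.uint8)


@dataclass
class LabeledBatch:
    """Encoded grids with rho labels plus packaged look-back sequences."""

    grids: list
    benchmark: object      # RoiBenchmark in standardized feature space
    scaler: object         # FeatureScaler fitted on the batch population
    X: np.ndarray          # (n_samples, look_back, 3)
    targets: np.ndarray    # (n_samples,)
    signals: list          # raw rho stream per image


def make_labeled_grids(specs, config: RunConfig | None = None,
                       target: str = "exudate") -> LabeledBatch:
    """Generate a batch, encode its segments, and package training samples.

    Per image: the green channel is extracted, tiled with the aperture
    field mask, and encoded; windows whose ``target`` mask ("exudate" or
    "vessel") coverage exceeds the ROI fraction feed the benchmark; each
    segment's rho against the benchmark (in standardized feature space) is
    its label. Look-back sequences are built per image (the recurrence
    never crosses image boundaries).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("at least one SyntheticSpec is required")
    if target not in ("exudate", "vessel"):
        raise ValueError("target must be 'exudate' or 'vessel'")
    config = config or RunConfig()

    from .detect import estimate_background
    from .segments import FeatureScaler

    grids, roi_features = [], []
    for spec in specs:
        rgb, vmask, emask = make_fundus(spec)
        gray = green_channel(rgb)
        bg = estimate_background(rgb, config.background_threshold)
        if target == "vessel":
            gray = (gray.astype(np.int64) * bg.mask).astype(np.uint8)
        grid = tile(gray, config.window, field_mask=bg.mask)
        encode_grid(grid, config)
        mask = emask if target == "exudate" else vmask
        roi_features.extend(collect_roi_features(grid, mask, config))
        grids.append(grid)
    if not roi_features:
        raise ValueError("no ground-truth-positive windows in the batch: "
                         "the ROI benchmark is undefined")
    scaler = FeatureScaler.fit(np.vstack([g.features for g in grids]))
    benchmark = build_benchmark([scaler.transform(f) for f in roi_features])

    all_X, all_t, signals = [], [], []
    for grid in grids:
        s = np.array([correlation_rho(f, benchmark.vector)
                      for f in scaler.transform(grid.features)])
        grid.rho = s
        grid.labels = [label_from_rho(v, config.rho_bins) for v in s]
        signals.append(s)
        X, t, _pos = build_sequences(s, config.look_back, for_training=True)
        if X.shape[0]:
            all_X.append(X)
            all_t.append(t)
    X = np.concatenate(all_X) if all_X else np.zeros((0, config.look_back, 3))
    targets = np.concatenate(all_t) if all_t else np.zeros(0)
    return LabeledBatch(grids, benchmark, scaler, X, targets, signals)
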