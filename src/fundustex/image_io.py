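"""Image and mask I/O, green-channel extraction, and CLAHE preprocessing.

Fundus photographs show the retinal vasculature with the best contrast in
the green channel, so the pipeline operates on that channel after
contrast-limited adaptive histogram equalization (CLAHE).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage import exposure

logger = logging.getLogger("fundustex")

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".ppm", ".pgm", ".jpg", ".jpeg"}


class ImageReadError(IOError):
    """Raised when a file cannot be read as a supported image."""


def read_image(path) -> np.ndarray:
    """Read an 8-bit image as a 2-D gray array or an (M, N, 3) RGB array.

    An alpha channel, if present, is dropped. Raises :class:`ImageReadError`
    naming the path for unreadable or unsupported files.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "P"):
                im = im.convert("RGB")
            elif im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if len(im.getbands()) >= 3 else "L")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageReadError(f"cannot read image file: {path}") from exc
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    """Write a gray (2-D) or RGB (M, N, 3) uint8 array losslessly."""
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def read_mask(path) -> np.ndarray:
    """Read a binary mask stored as an image; any nonzero pixel maps to 1."""
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a 0/1 mask as an 8-bit image with values 0/255."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    write_image(path, (mask * 255).astype(np.uint8))


def green_channel(rgb: np.ndarray) -> np.ndarray:
    """Project an RGB image onto its green channel.

    Raises ValueError for single-channel input: a gray image has no green
    channel and extraction should simply be skipped.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] < 3:
        raise ValueError(
            "green_channel expects an (M, N, 3) RGB array; "
            "for grayscale input skip channel extraction"
        )
    return np.ascontiguousarray(rgb[:, :, 1])


def clahe(img: np.ndarray, clip_limit: float = 0.01,
          tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` is the normalized clipping fraction; ``tile_grid`` the
    number of contextual tiles along (rows, cols). Returns uint8 in [0, 255].
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("clahe expects a non-empty 2-D gray image")
    if img.min() == img.max():
        # no contrast to redistribute
        return img.astype(np.uint8).copy()
    kernel = (max(1, img.shape[0] // tile_grid[0]),
              max(1, img.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(img.astype(np.uint8), kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Green-channel projection for RGB input; gray input passes through."""
    img = np.asarray(img)
    return green_channel(img) if img.ndim == 3 else img
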