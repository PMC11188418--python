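"""Image and mask data model, file I/O, grayscale conversion, padding.

Conventions used throughout the package:

* A *grayscale image* is a 2-D ``numpy.ndarray`` of ``uint8``, indexed
  ``(row, col)``, 0-based, origin at the top-left.
* A *color image* is an ``(H, W, 3)`` ``uint8`` array in RGB channel order
  on the same grid convention.
* A *binary mask* is a 2-D ``uint8`` array of exactly ``{0, 1}``, the same
  shape as the image it partners; 1 marks the fruit (foreground).

All public functions validate their inputs against these conventions and
raise ``ValueError`` on violation.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "read_image",
    "write_image",
    "to_grayscale",
    "pad_replicate",
    "as_grayscale_image",
    "as_color_image",
    "as_binary_mask",
]

#: ITU-R BT.601 luminance weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def as_grayscale_image(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as a 2-D uint8 grayscale image."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("image must have at least one pixel")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"grayscale image must be integer-valued, got {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("grayscale intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_color_image(img: np.ndarray) -> np.ndarray:
    """Validate and return ``img`` as an (H, W, 3) uint8 RGB image."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"color image must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("image must have at least one pixel")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"color image must be integer-valued, got {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("color intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_binary_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate ``mask`` as a {0, 1} uint8 array, optionally against ``shape``."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask values must be exactly 0 or 1")
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match image shape {tuple(shape)}")
    return arr.astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or JPEG raster from ``path``.

    Returns an ``(H, W, 3)`` uint8 array for color files and an ``(H, W)``
    uint8 array for single-channel files.  Palette and RGBA files are
    converted to RGB; 16-bit grayscale inputs are rescaled to [0, 255] by
    integer division (``value // 256``).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    undecodable content.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("1", "L"):
                return np.asarray(im.convert("L"), dtype=np.uint8)
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                raw = np.asarray(im, dtype=np.uint32)
                return (raw // 256).clip(0, 255).astype(np.uint8)
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"cannot decode image file: {path}") from exc
    except OSError as exc:
        raise ValueError(f"corrupt or truncated image file: {path}") from exc


def write_image(
    img: np.ndarray,
    path: str | os.PathLike,
    *,
    jpeg_quality: int | None = None,
) -> None:
    """Write an image to ``path``.

    PNG output (the default, and whenever the suffix is ``.png``) is
    lossless: ``read_image(path)`` recovers the array bit-for-bit.  A
    ``.jpg``/``.jpeg`` suffix selects JPEG; ``jpeg_quality`` (default 95)
    only applies there.

    Raises ``FileNotFoundError`` when the parent directory does not exist.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = as_grayscale_image(arr)
        im = Image.fromarray(arr, mode="L")
    else:
        arr = as_color_image(arr)
        im = Image.fromarray(arr, mode="RGB")
    if path.suffix.lower() in (".jpg", ".jpeg"):
        im.save(path, format="JPEG", quality=95 if jpeg_quality is None else int(jpeg_quality))
    else:
        im.save(path, format="PNG")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit luminance.

    Per pixel: ``round(0.299 R + 0.587 G + 0.114 B)`` with round-half-up
    (equivalent to round-half-away-from-zero on the nonnegative range),
    clamped to [0, 255].  A grayscale input is returned unchanged.
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return as_grayscale_image(arr)
    arr = as_color_image(arr)
    wr, wg, wb = LUMA_WEIGHTS
    lum = wr * arr[..., 0] + wg * arr[..., 1] + wb * arr[..., 2]
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def pad_replicate(img: np.ndarray, margin: int) -> np.ndarray:
    """Pad a grayscale image by ``margin`` pixels on every side, replicating
    the nearest edge pixel.  ``margin`` must be >= 0; 0 returns a copy."""
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    arr = as_grayscale_image(img)
    if margin == 0:
        return arr.copy()
    return np.pad(arr, margin, mode="edge")
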