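"""Independent straight-line reference implementations used as oracles.

Everything here is deliberately naive (pure-Python loops, explicit
coordinate enumeration) and shares no code with the package beyond numpy
array indexing, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

# Clockwise compass offsets starting at the top-left diagonal,
# re-derived here independently of the package's table.
CLOCKWISE_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def ref_dispersion(values) -> float:
    """Sum of squared deviations over (count x mean), as a percent."""
    values = [float(v) for v in values]
    mean = sum(values) / len(values)
    if mean == 0.0:
        return 0.0
    ssd = sum((v - mean) ** 2 for v in values)
    return ssd / (len(values) * mean) * 100.0


def ref_mad(values) -> float:
    """Mean absolute deviation from the mean."""
    values = [float(v) for v in values]
    mean = sum(values) / len(values)
    return sum(abs(v - mean) for v in values) / len(values)


def _clamped(img: np.ndarray, r: int, c: int) -> float:
    """Pixel value with replicate (edge-clamped) out-of-bounds handling."""
    h, w = img.shape
    return float(img[min(max(r, 0), h - 1), min(max(c, 0), w - 1)])


def ref_rlbp_code(
    img: np.ndarray,
    r: int,
    c: int,
    threshold: float = 0.15,
    ray_length: int = 2,
    zero_cv_policy: int = 1,
) -> int:
    """Naive per-direction R-LBP code with replicate border handling."""
    code = 0
    for dr, dc in CLOCKWISE_OFFSETS:
        ray = [
            _clamped(img, r + k * dr, c + k * dc) for k in range(1, ray_length + 2)
        ]
        cva = ref_dispersion(ray)
        cvb = ref_dispersion([_clamped(img, r, c)] + ray)
        if cva == 0.0:
            bit = 0 if cvb == 0.0 else zero_cv_policy
        else:
            bit = 1 if abs(cva - cvb) / cva > threshold else 0
        code = code * 2 + bit
    return code


def ref_rlbp_image(img: np.ndarray, threshold: float = 0.15, ray_length: int = 2) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            out[r, c] = ref_rlbp_code(img, r, c, threshold, ray_length)
    return out


def ref_lbp_code(img: np.ndarray, r: int, c: int) -> int:
    code = 0
    center = _clamped(img, r, c)
    for dr, dc in CLOCKWISE_OFFSETS:
        code = code * 2 + (1 if _clamped(img, r + dr, c + dc) >= center else 0)
    return code


def ref_lbp_image(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            out[r, c] = ref_lbp_code(img, r, c)
    return out


def ref_region_centers(h: int, w: int) -> list[tuple[int, int]]:
    """The nine quarter-point grid centers of an h x w rectangle
    (row-major), by direct arithmetic."""
    rows = [math.floor(h * k / 4 + 0.5) for k in (1, 2, 3)]
    cols = [math.floor(w * k / 4 + 0.5) for k in (1, 2, 3)]
    return [(r, c) for r in rows for c in cols]


def ref_ray_coords(
    center: tuple[int, int],
    offset: tuple[int, int],
    window: tuple[int, int, int, int],
) -> list[tuple[int, int]]:
    """Coordinates of a half-ray from center inside a (top, left, bottom,
    right) window, by explicit stepping."""
    top, left, bottom, right = window
    r, c = center
    coords = []
    while top <= r < bottom and left <= c < right:
        coords.append((r, c))
        r += offset[0]
        c += offset[1]
    return coords


def ref_luminance(r: int, g: int, b: int) -> float:
    """Unrounded BT.601 luminance, via the Fraction module for exactness."""
    from fractions import Fraction

    return float(
        Fraction(299, 1000) * r + Fraction(587, 1000) * g + Fraction(114, 1000) * b
    )
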