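"""Peel-roughness metric: directional pixel deviations over nine sampling regions.

The roughness of a fruit peel is quantified on the grayscale bounding
rectangle of the fruit.  The rectangle's sides are divided into four equal
parts; the nine interior grid intersection points are the centers of nine
sampling regions, each a quarter-of-the-rectangle-sized window.  Within a
region, eight half-rays leave the center toward the 8 compass neighbors;
along each ray the mean absolute deviation of the pixel intensities from
the ray mean is the directional deviation

    D_i = sum_j |X_j - X'| / N        (X' the ray mean, N the ray length),

the region value P_i is the mean of its eight D_i, and the overall
roughness is the mean of the nine P_i.  Rougher peel -> larger local
grayscale variation -> larger roughness; the metric decreases as the fruit
ripens and epicuticular wax smooths the peel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_core import as_binary_mask

__all__ = [
    "DIRECTIONS",
    "Direction",
    "SamplingRegion",
    "RoughnessReport",
    "directional_deviation",
    "region_rays",
    "sampling_regions",
    "region_roughness",
    "peel_roughness",
    "mask_bounding_rect",
]

MIN_RECT_SIDE = 12  # guarantees every region window is >= 3x3


def _as_intensity_array(img) -> np.ndarray:
    """2-D numeric array of intensities.  Unlike the 8-bit image model,
    the roughness metric is a pure measurement and accepts float arrays
    (e.g. un-clamped pipeline doubles); no range restriction is applied."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"need a non-empty 2-D intensity array, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class Direction:
    """One of the 8 compass neighbors, numbered clockwise from the
    top-left diagonal: 1=NW, 2=N, 3=NE, 4=E, 5=SE, 6=S, 7=SW, 8=W."""

    id: int
    offset: tuple[int, int]  # (drow, dcol)


#: The eight directions in clockwise numbering order (index 0 <-> id 1).
DIRECTIONS: tuple[Direction, ...] = (
    Direction(1, (-1, -1)),
    Direction(2, (-1, 0)),
    Direction(3, (-1, +1)),
    Direction(4, (0, +1)),
    Direction(5, (+1, +1)),
    Direction(6, (+1, 0)),
    Direction(7, (+1, -1)),
    Direction(8, (0, -1)),
)


@dataclass(frozen=True)
class SamplingRegion:
    """One of the nine roughness sampling windows, in image coordinates.

    ``center`` is a grid intersection point of the quartered bounding
    rectangle; the window is the quarter-rectangle-sized box centered
    there, clipped to the rectangle.  ``top``/``left`` are inclusive,
    ``bottom``/``right`` exclusive.
    """

    center: tuple[int, int]
    top: int
    left: int
    bottom: int
    right: int

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left

    def contains(self, row: int, col: int) -> bool:
        return self.top <= row < self.bottom and self.left <= col < self.right


@dataclass(frozen=True)
class RoughnessReport:
    """Full roughness decomposition: 9x8 directional deviations D_i,
    nine region values P_i, and the overall scalar (mean of the P_i)."""

    per_region_di: np.ndarray  # shape (9, 8), intensity units
    per_region_pi: np.ndarray  # shape (9,)
    overall: float

    def to_dict(self) -> dict:
        return {
            "per_region_di": self.per_region_di.tolist(),
            "per_region_pi": self.per_region_pi.tolist(),
            "overall": self.overall,
        }


def directional_deviation(values) -> float:
    """Mean absolute deviation of an ordered intensity list from its mean.

    Requires at least two values; returns ``sum(|x - mean|) / N``.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"need a 1-D list of >= 2 intensities, got shape {arr.shape}")
    return float(np.abs(arr - arr.mean()).sum() / arr.size)


def mask_bounding_rect(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Bounding rectangle (top, left, bottom, right; bottom/right exclusive)
    of the nonzero pixels of a mask.  Raises on an all-zero mask."""
    m = as_binary_mask(mask)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        raise ValueError("mask has no nonzero pixels")
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sampling_regions(img: np.ndarray, mask: np.ndarray | None = None) -> list[SamplingRegion]:
    """The nine sampling regions of an image (or of its mask's bounding
    rectangle when ``mask`` is given).

    Each side of the H x W rectangle is divided into four equal parts; the
    3 x 3 interior intersection points, at local offsets
    ``round(H*k/4), round(W*k/4)`` for k in {1, 2, 3}, are the region
    centers.  Each window is ``ceil(H/4) x ceil(W/4)``, centered on its
    point and clipped to the rectangle.  Regions are returned row-major
    over the center grid.

    Both rectangle sides must be >= 12 pixels.
    """
    arr = _as_intensity_array(img)
    if mask is not None:
        top, left, bottom, right = mask_bounding_rect(as_binary_mask(mask, arr.shape))
    else:
        top, left, bottom, right = 0, 0, arr.shape[0], arr.shape[1]
    h, w = bottom - top, right - left
    if h < MIN_RECT_SIDE or w < MIN_RECT_SIDE:
        raise ValueError(
            f"bounding rectangle {h}x{w} too small; both sides must be >= {MIN_RECT_SIDE}"
        )
    win_h = math.ceil(h / 4)
    win_w = math.ceil(w / 4)
    row_centers = [_round_half_up(h * k / 4) for k in (1, 2, 3)]
    col_centers = [_round_half_up(w * k / 4) for k in (1, 2, 3)]
    regions = []
    for rc in row_centers:
        for cc in col_centers:
            r0 = max(rc - win_h // 2, 0)
            c0 = max(cc - win_w // 2, 0)
            r1 = min(r0 + win_h, h)
            c1 = min(c0 + win_w, w)
            regions.append(
                SamplingRegion(
                    center=(top + rc, left + cc),
                    top=top + r0,
                    left=left + c0,
                    bottom=top + r1,
                    right=left + c1,
                )
            )
    return regions


def region_rays(region: SamplingRegion, img: np.ndarray) -> list[np.ndarray]:
    """The eight directional half-rays of a sampling region.

    For each direction (clockwise numbering), the ray starts at the region
    center and steps by the direction offset until it would leave the
    region window; the center pixel is included.  Every ray must have
    length >= 2 (guaranteed for windows >= 3x3 with an interior center).
    """
    arr = _as_intensity_array(img)
    if not region.contains(*region.center):
        raise ValueError("region center lies outside its window")
    rays = []
    for d in DIRECTIONS:
        dr, dc = d.offset
        r, c = region.center
        vals = []
        while region.contains(r, c):
            vals.append(arr[r, c])
            r += dr
            c += dc
        if len(vals) < 2:
            raise ValueError(
                f"direction {d.id} ray has length {len(vals)}; window too small"
            )
        rays.append(np.asarray(vals, dtype=np.float64))
    return rays


def region_roughness(region: SamplingRegion, img: np.ndarray) -> float:
    """Region value P_i: the mean of the eight directional deviations."""
    dis = [directional_deviation(ray) for ray in region_rays(region, img)]
    return float(np.mean(dis))


def peel_roughness(img: np.ndarray, mask: np.ndarray | None = None) -> RoughnessReport:
    """Overall peel roughness of an image (optionally restricted to the
    bounding rectangle of a fruit mask).

    Ray pixels are read from the image irrespective of the mask: the metric
    operates on the fruit's bounding rectangle, not its silhouette.
    """
    regions = sampling_regions(img, mask)
    per_di = np.empty((9, 8), dtype=np.float64)
    for i, region in enumerate(regions):
        for j, ray in enumerate(region_rays(region, img)):
            per_di[i, j] = directional_deviation(ray)
    per_pi = per_di.mean(axis=1)
    return RoughnessReport(per_region_di=per_di, per_region_pi=per_pi, overall=float(per_pi.mean()))
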