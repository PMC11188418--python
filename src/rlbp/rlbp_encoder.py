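"""R-LBP per-pixel texture encoding and the classic LBP baseline.

Classic LBP encodes each pixel as an 8-bit word from threshold comparisons
of its 3x3 neighbors against the center.  The R-LBP (roughness LBP)
variant instead asks, per direction, whether the target pixel meaningfully
changes the *dispersion* of the outward pixel ray in that direction:

    CVa = (sum (X_i - X')^2) / (n  X') x 100    over the ray pixels,
    CVb = the same quantity with the target pixel prepended,

and emits bit 1 when |CVa - CVb| / CVa exceeds a threshold (15% by
default) -- i.e. when the target pixel sits on strong local texture in
that direction.  The eight bits, direction 1 (top-left, clockwise) as the
most significant, form the output code.  Because CVa and CVb both scale
linearly under an intensity scaling x -> kx, the code is scale-invariant.

The dispersion here is deliberately the sum of *squared* deviations over
(count x mean) -- an index-of-dispersion-like percent quantity, not the
textbook standard-deviation-over-mean coefficient of variation.  Only the
relative change between CVa and CVb enters the encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roughness import DIRECTIONS, Direction, _as_intensity_array

__all__ = [
    "RLBPParams",
    "dispersion",
    "direction_arrays",
    "encode_pixel",
    "rlbp_transform",
    "lbp_transform",
]


@dataclass(frozen=True)
class RLBPParams:
    """Configuration of the R-LBP encoding.

    threshold
        Relative-change threshold on the dispersion, as a fraction in
        (0, 1).  Bit 1 is emitted when ``|CVa - CVb| / CVa`` is *strictly*
        greater than it.  Default 0.15.
    ray_length
        Outward pixels per direction beyond the reference pixel; the CVa
        array holds ``ray_length + 1`` pixels.  Default 2 (3-pixel rays).
    border_policy
        ``"replicate_pad"`` (default) pads the image by ``ray_length + 1``
        replicated edge pixels so every pixel receives a code;
        ``"zero_border"`` emits code 0 for pixels whose neighborhood
        leaves the image.
    zero_cv_policy
        Bit emitted in the degenerate case CVa = 0 with CVb > 0 (the
        target pixel introduces all the variation, an unboundedly large
        relative change).  Default 1.  CVa = CVb = 0 always emits 0.
    """

    threshold: float = 0.15
    ray_length: int = 2
    border_policy: str = "replicate_pad"
    zero_cv_policy: int = 1

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.ray_length < 1:
            raise ValueError(f"ray_length must be >= 1, got {self.ray_length}")
        if self.border_policy not in ("replicate_pad", "zero_border"):
            raise ValueError(f"unknown border_policy {self.border_policy!r}")
        if self.zero_cv_policy not in (0, 1):
            raise ValueError(f"zero_cv_policy must be 0 or 1, got {self.zero_cv_policy}")

    @property
    def margin(self) -> int:
        """Neighborhood reach of the encoding in pixels."""
        return self.ray_length + 1


def dispersion(values) -> float:
    """Dispersion percent of an ordered nonnegative intensity list:
    ``(sum (x - mean)^2) / (n * mean) * 100``.

    Returns 0 for the all-zero list (the only way the mean of nonnegative
    intensities can vanish).  Requires length >= 2.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"need a 1-D list of >= 2 values, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("dispersion is defined for nonnegative intensities")
    mean = arr.mean()
    if mean == 0.0:
        return 0.0
    return float(((arr - mean) ** 2).sum() / (arr.size * mean) * 100.0)


def direction_arrays(
    img: np.ndarray,
    pixel: tuple[int, int],
    direction: Direction,
    params: RLBPParams = RLBPParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """The (CVa, CVb) pixel arrays of one direction at one target pixel.

    The CVa array holds the intensities at offsets ``1*d .. (ray_length+1)*d``
    from the target pixel -- the reference pixel and its collinear outward
    continuation.  The CVb array is the CVa array with the target pixel's
    own intensity prepended.  The whole ray must lie inside the image.
    """
    arr = _as_intensity_array(img)
    r, c = pixel
    dr, dc = direction.offset
    m = params.margin
    end_r, end_c = r + m * dr, c + m * dc
    if not (0 <= r < arr.shape[0] and 0 <= c < arr.shape[1]):
        raise ValueError(f"target pixel {pixel} outside image")
    if not (0 <= end_r < arr.shape[0] and 0 <= end_c < arr.shape[1]):
        raise ValueError(
            f"direction {direction.id} ray from {pixel} leaves the image"
        )
    cva = np.array(
        [arr[r + k * dr, c + k * dc] for k in range(1, m + 1)], dtype=np.float64
    )
    cvb = np.concatenate(([np.float64(arr[r, c])], cva))
    return cva, cvb


def _bit_from_cvs(cva: float, cvb: float, params: RLBPParams) -> int:
    if cva == 0.0:
        return 0 if cvb == 0.0 else params.zero_cv_policy
    return 1 if abs(cva - cvb) / cva > params.threshold else 0


def encode_pixel(
    img: np.ndarray,
    pixel: tuple[int, int],
    params: RLBPParams = RLBPParams(),
) -> int:
    """R-LBP code of one pixel whose full neighborhood lies in the image.

    For each of the eight directions in clockwise numbering order the
    dispersion criterion emits one bit; direction 1 is the most
    significant bit of the returned 8-bit code.
    """
    code = 0
    for d in DIRECTIONS:
        cva_arr, cvb_arr = direction_arrays(img, pixel, d, params)
        bit = _bit_from_cvs(dispersion(cva_arr), dispersion(cvb_arr), params)
        code = (code << 1) | bit
    return code


def _dispersion_grid(stack: np.ndarray) -> np.ndarray:
    """Vectorized ``dispersion`` over axis 0 of an (n, H, W) float stack."""
    mean = stack.mean(axis=0)
    ssd = ((stack - mean) ** 2).sum(axis=0)
    out = np.zeros_like(mean)
    nz = mean != 0.0
    out[nz] = ssd[nz] / (stack.shape[0] * mean[nz]) * 100.0
    return out


def rlbp_transform(img: np.ndarray, params: RLBPParams = RLBPParams()) -> np.ndarray:
    """R-LBP code image of ``img`` (same shape, uint8 codes).

    Under ``replicate_pad`` the image is edge-padded by ``ray_length + 1``
    first so every pixel is encoded; under ``zero_border`` pixels whose
    neighborhood leaves the image get code 0.
    """
    arr = _as_intensity_array(img).astype(np.float64)
    if np.any(arr < 0):
        raise ValueError("intensities must be nonnegative")
    h, w = arr.shape
    m = params.margin
    padded = np.pad(arr, m, mode="edge")
    code = np.zeros((h, w), dtype=np.uint8)
    x0 = padded[m : m + h, m : m + w]
    for idx, d in enumerate(DIRECTIONS):
        dr, dc = d.offset
        rays = np.stack(
            [
                padded[m + k * dr : m + k * dr + h, m + k * dc : m + k * dc + w]
                for k in range(1, m + 1)
            ]
        )
        cva = _dispersion_grid(rays)
        cvb = _dispersion_grid(np.concatenate((x0[None], rays)))
        bit = np.zeros((h, w), dtype=np.uint8)
        nz = cva != 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            bit[nz] = np.abs(cva[nz] - cvb[nz]) / cva[nz] > params.threshold
        if params.zero_cv_policy:
            bit[~nz & (cvb > 0.0)] = 1
        code |= bit << (7 - idx)
    if params.border_policy == "zero_border":
        code[:m], code[-m:] = 0, 0
        code[:, :m], code[:, -m:] = 0, 0
    return code


def lbp_transform(img: np.ndarray) -> np.ndarray:
    """Classic 3x3 LBP code image: bit 1 where neighbor >= center, same
    clockwise bit order and replicate-pad border policy as R-LBP."""
    arr = _as_intensity_array(img).astype(np.float64)
    h, w = arr.shape
    padded = np.pad(arr, 1, mode="edge")
    center = padded[1 : 1 + h, 1 : 1 + w]
    code = np.zeros((h, w), dtype=np.uint8)
    for idx, d in enumerate(DIRECTIONS):
        dr, dc = d.offset
        neigh = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w]
        code |= (neigh >= center).astype(np.uint8) << (7 - idx)
    return code
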