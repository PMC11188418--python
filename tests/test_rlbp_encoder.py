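import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rlbp.image_core import pad_replicate
from rlbp.rlbp_encoder import (
    RLBPParams,
    direction_arrays,
    dispersion,
    encode_pixel,
    lbp_transform,
    rlbp_transform,
)
from rlbp.roughness import DIRECTIONS
from reference import ref_dispersion, ref_lbp_image, ref_rlbp_code, ref_rlbp_image


def _rotate_bits(codes: np.ndarray, k: int) -> np.ndarray:
    """Cyclic rotation of each 8-bit pattern by k positions toward MSB."""
    c = codes.astype(np.uint16)
    return (((c << k) | (c >> (8 - k))) & 0xFF).astype(np.uint8)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"threshold": 0.0},
            {"threshold": 1.0},
            {"ray_length": 0},
            {"border_policy": "mirror"},
            {"zero_cv_policy": 2},
        ],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            RLBPParams(**kwargs)

    def test_margin(self):
        assert RLBPParams().margin == 3
        assert RLBPParams(ray_length=4).margin == 5


class TestDispersion:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([7, 7, 7, 7], 0.0),
            ([10, 20, 30], 200 / (3 * 20) * 100),  # 333.33...
            ([0, 0, 0], 0.0),
        ],
    )
    def test_known_values(self, values, expected):
        assert dispersion(values) == pytest.approx(expected, abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dispersion([4])

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        values=st.lists(st.integers(0, 255), min_size=2, max_size=8),
        k=st.floats(0.01, 50.0),
    )
    def test_matches_reference_and_scales_linearly(self, values, k):
        d = dispersion(values)
        assert d == pytest.approx(ref_dispersion(values), abs=1e-9)
        assert dispersion([k * v for v in values]) == pytest.approx(k * d, rel=1e-9, abs=1e-12)


class TestDirectionArrays:
    def test_east_ray(self):
        img = np.array([[5, 10, 20, 40]], dtype=np.uint8)
        cva, cvb = direction_arrays(img, (0, 0), DIRECTIONS[3])
        assert cva.tolist() == [10.0, 20.0, 40.0]
        assert cvb.tolist() == [5.0, 10.0, 20.0, 40.0]

    def test_diagonal_picks_marked_pixels(self):
        img = np.zeros((7, 7), np.uint8)
        marks = [(2, 4), (1, 5), (0, 6)]  # NE ray from (3, 3)
        for i, (r, c) in enumerate(marks, start=1):
            img[r, c] = 10 * i
        cva, _ = direction_arrays(img, (3, 3), DIRECTIONS[2])
        assert cva.tolist() == [10.0, 20.0, 30.0]

    def test_constant_image_constant_arrays(self):
        img = np.full((9, 9), 42, np.uint8)
        cva, cvb = direction_arrays(img, (4, 4), DIRECTIONS[0])
        assert np.all(cva == 42.0) and np.all(cvb == 42.0)

    def test_out_of_bounds_raises(self):
        img = np.zeros((5, 5), np.uint8)
        with pytest.raises(ValueError):
            direction_arrays(img, (4, 4), DIRECTIONS[4])  # SE leaves the image


class TestEncodePixel:
    def test_constant_image_zero(self):
        img = np.full((9, 9), 100, np.uint8)
        assert encode_pixel(img, (4, 4)) == 0

    def test_single_direction_patch_encodes_128(self):
        """A patch where only direction 1 (NW, the most significant bit)
        exceeds the dispersion-change criterion encodes to 10000000b.

        Directions 2-8 carry the ray (90, 100, 110) whose dispersion is
        nearly unchanged by the target value 110; direction 1 carries
        (105, 110, 115), where the target equals the ray mean, changing
        the dispersion by exactly 25% > 15%.
        """
        img = np.full((9, 9), 0, np.uint8)
        img[4, 4] = 110
        ray_other = (90, 100, 110)
        ray_nw = (105, 110, 115)
        for d in DIRECTIONS:
            vals = ray_nw if d.id == 1 else ray_other
            for k, v in enumerate(vals, start=1):
                img[4 + k * d.offset[0], 4 + k * d.offset[1]] = v
        assert ref_rlbp_code(img, 4, 4) == 128  # oracle agrees on the construction
        assert encode_pixel(img, (4, 4)) == 128

    def test_matches_naive_oracle_on_random_pixels(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        for r in range(3, 9):
            for c in range(3, 9):
                assert encode_pixel(img, (r, c)) == ref_rlbp_code(img, r, c)

    def test_zero_cv_policy_switch(self):
        img = np.full((9, 9), 100, np.uint8)
        img[4, 4] = 120  # every ray constant: CVa=0, CVb>0 in all directions
        assert encode_pixel(img, (4, 4), RLBPParams(zero_cv_policy=1)) == 255
        assert encode_pixel(img, (4, 4), RLBPParams(zero_cv_policy=0)) == 0


class TestTransforms:
    def test_constant_image_codes(self):
        img = np.full((10, 10), 50, np.uint8)
        assert np.all(rlbp_transform(img) == 0)
        assert np.all(lbp_transform(img) == 255)

    def test_lbp_single_bright_pixel(self):
        img = np.zeros((9, 9), np.uint8)
        img[4, 4] = 255
        assert lbp_transform(img)[4, 4] == 0

    @pytest.mark.parametrize("size", [8, 16, 31, 64])
    def test_rlbp_matches_naive_oracle(self, size):
        img = np.random.default_rng(size).integers(0, 256, (size, size)).astype(np.uint8)
        assert np.array_equal(rlbp_transform(img), ref_rlbp_image(img))

    @pytest.mark.parametrize("size", [8, 16, 31, 64])
    def test_lbp_matches_naive_oracle(self, size):
        img = np.random.default_rng(size + 1).integers(0, 256, (size, size)).astype(np.uint8)
        assert np.array_equal(lbp_transform(img), ref_lbp_image(img))

    def test_rlbp_nondefault_params_match_oracle(self):
        img = np.random.default_rng(7).integers(0, 256, (20, 20)).astype(np.uint8)
        params = RLBPParams(threshold=0.3, ray_length=3)
        got = rlbp_transform(img, params)
        assert np.array_equal(got, ref_rlbp_image(img, threshold=0.3, ray_length=3))

    def test_zero_border_policy(self, random_gray):
        params = RLBPParams(border_policy="zero_border")
        out = rlbp_transform(random_gray, params)
        m = params.margin
        assert np.all(out[:m] == 0) and np.all(out[-m:] == 0)
        assert np.all(out[:, :m] == 0) and np.all(out[:, -m:] == 0)
        interior = rlbp_transform(random_gray)[m:-m, m:-m]
        assert np.array_equal(out[m:-m, m:-m], interior)

    def test_output_range_and_shape(self, rng):
        img = rng.integers(0, 256, (13, 29)).astype(np.uint8)
        for out in (rlbp_transform(img), lbp_transform(img)):
            assert out.shape == img.shape and out.dtype == np.uint8

    def test_transform_equals_padded_per_pixel_encoding(self, random_gray):
        """Replicate-pad then per-pixel encode equals the whole-image
        transform at every position (vectorised vs straight-line route)."""
        params = RLBPParams()
        padded = pad_replicate(random_gray, params.margin)
        out = rlbp_transform(random_gray, params)
        for r in range(16):
            for c in range(16):
                assert out[r, c] == encode_pixel(
                    padded, (r + params.margin, c + params.margin), params
                )

    def test_determinism(self, random_gray):
        a = rlbp_transform(random_gray)
        b = rlbp_transform(random_gray.copy())
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("transform", [rlbp_transform, lbp_transform])
    def test_rot90_equivariance_with_bit_rotation(self, transform, rng):
        """Rotating the image 90 degrees permutes the eight clockwise
        directions by two positions, so interior codes rotate their bit
        patterns by two."""
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        m = 3
        direct = transform(np.rot90(img))
        from_codes = _rotate_bits(np.rot90(transform(img)), 2)
        assert np.array_equal(direct[m:-m, m:-m], from_codes[m:-m, m:-m])

    def test_scale_invariance_on_floats(self):
        """R-LBP codes are unchanged under x -> kx on float doubles (both
        dispersions scale by k), unlike the raw intensities.  Interior
        pixels only: replicate padding makes border rays exactly constant,
        where the CVa=0 classification is at the mercy of float rounding."""
        rng = np.random.default_rng(3)
        img = rng.uniform(1.0, 255.0, (16, 16))
        m = RLBPParams().margin
        a = rlbp_transform(img)[m:-m, m:-m]
        b = rlbp_transform(2.75 * img)[m:-m, m:-m]
        assert np.array_equal(a, b)
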