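import numpy as np
import pytest
from scipy import ndimage as ndi

from _oracles import f1_image_loop, f1_scalar
from conftest import TEST_SHAPE
from endofeat.descriptors import (
    DESCRIPTOR_IDS,
    DescriptorParams,
    compute_all,
    compute_descriptor,
    descriptor_f1,
)
from endofeat.primitives import InvalidInputError
from endofeat.synthetic import Ellipse, SceneSpec, generate_frame


def _pixel(r, g, b, roi=1):
    img = np.full((1, 1, 3), (r, g, b), dtype=np.uint8)
    return float(descriptor_f1(img, np.array([[roi]], dtype=bool))[0, 0])


class TestF1:
    def test_matches_scalar_trace_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
            roi = rng.random((16, 16)) > 0.2
            expected = f1_image_loop(img, roi)
            got = descriptor_f1(img, roi)
            assert np.abs(got - expected).max() < 1e-9

    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 1, 1), 0.98 / 1.08),  # saturated blood red: c1=1, c2=1
            ((100, 100, 100), f1_scalar(100, 100, 100, 1)),  # gray: weak ratio
            ((150, 22, 28), f1_scalar(150, 22, 28, 1)),  # generator blood color
        ],
    )
    def test_frozen_pixel_values(self, rgb, expected):
        assert _pixel(*rgb) == pytest.approx(expected, abs=1e-12)

    def test_low_red_cleared(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            g, b = rng.integers(0, 256, 2)
            assert _pixel(int(rng.integers(0, 30)), int(g), int(b)) == 0.0

    def test_outside_roi_cleared(self):
        assert _pixel(255, 1, 1, roi=0) == 0.0

    def test_monotone_in_red_channel(self):
        for g, b in [(1, 1), (20, 30), (80, 80), (120, 100)]:
            values = [_pixel(r, g, b) for r in range(30, 256)]
            assert all(v2 >= v1 for v1, v2 in zip(values, values[1:]))

    def test_pure_function(self, crisp_frame):
        img, _, roi = crisp_frame
        np.testing.assert_array_equal(descriptor_f1(img, roi), descriptor_f1(img, roi))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            descriptor_f1(np.zeros((4, 4, 3), np.uint8), np.ones((5, 5), bool))


def _uniform_field(color, shape=(96, 96)):
    img = np.full(shape + (3,), color, dtype=np.uint8)
    roi = np.ones(shape, dtype=bool)
    return img, roi


class TestPerFeatureContracts:
    def test_unknown_id_rejected(self):
        img, roi = _uniform_field((100, 100, 100))
        with pytest.raises(InvalidInputError):
            compute_descriptor("F10", img, roi)

    def test_f8_above_half_when_red_covers_60_percent(self):
        img, roi = _uniform_field((100, 100, 100), shape=(100, 100))
        img[:60] = (180, 100, 60)  # wide red on 60% of the roi
        value = compute_descriptor("F8", img, roi)
        assert np.unique(value[roi]).size == 1
        assert value[0, 0] > 0.5

    def test_f8_below_half_when_red_covers_40_percent(self):
        img, roi = _uniform_field((100, 100, 100), shape=(100, 100))
        img[:40] = (180, 100, 60)
        assert compute_descriptor("F8", img, roi)[0, 0] < 0.5

    def test_f8_ignores_highlight_pixels(self):
        # 50/50 red vs highlight: highlights are excluded, so red covers all
        # of the clear area and the value goes above 0.5
        img, roi = _uniform_field((245, 245, 245), shape=(100, 100))
        img[:50] = (180, 100, 60)
        assert compute_descriptor("F8", img, roi)[0, 0] > 0.5

    def test_f7_large_component_excluded(self):
        spec = SceneSpec(
            shape=TEST_SHAPE,
            fov_radius=120.0,
            texture_noise_std=0.0,
            blood_blobs=(Ellipse(center=(144.0, 180.0), axes=(40.0, 50.0)),),
            seed=1,
        )
        img, blood, fov = generate_frame(spec)
        assert blood.sum() > 0.01 * fov.sum()  # one blob covering > 1% of roi
        assert not compute_descriptor("F7", img, fov).any()

    def test_f7_keeps_small_spots(self):
        spec = SceneSpec(
            shape=TEST_SHAPE,
            fov_radius=120.0,
            texture_noise_std=0.0,
            blood_blobs=tuple(
                Ellipse(center=(100.0 + 30 * k, 150.0), axes=(4.0, 4.0))
                for k in range(3)
            ),
            seed=1,
        )
        img, blood, fov = generate_frame(spec)
        f7 = compute_descriptor("F7", img, fov)
        assert f7[blood].mean() > 0.5
        assert not f7[~blood].any()

    def test_f2_smoothness_gate_monotone_in_noise(self):
        blob = Ellipse(center=(144.0, 180.0), axes=(40.0, 50.0))
        frames = {}
        for std in (0.0, 25.0):
            spec = SceneSpec(
                shape=TEST_SHAPE, fov_radius=120.0, texture_noise_std=0.0,
                blood_blobs=(Ellipse(**{**blob.__dict__, "noise_std": std}),), seed=5,
            )
            img, blood, fov = generate_frame(spec)
            frames[std] = compute_descriptor("F2", img, fov)[blood].mean()
        assert frames[0.0] > frames[25.0]

    def test_f9_higher_on_blurred_image(self):
        # checkerboard with 32-px squares: sharp edges, high variance
        tiles = np.indices((96, 96)).sum(axis=0) // 32 % 2
        img = np.where(tiles[..., None] == 1, 230, 25).astype(np.uint8)
        img = np.repeat(img, 3, axis=2)
        roi = np.ones((96, 96), dtype=bool)
        sharp = compute_descriptor("F9", img, roi)[0, 0]
        blurred_img = np.clip(
            ndi.gaussian_filter(img.astype(float), sigma=(5, 5, 0)), 0, 255
        ).astype(np.uint8)
        blurred = compute_descriptor("F9", blurred_img, roi)[0, 0]
        assert blurred > sharp

    def test_f3_requires_sharp_boundary(self, crisp_frame):
        img, blood, roi = crisp_frame
        f3 = compute_descriptor("F3", img, roi)
        assert f3[blood].mean() > 0.5  # crisp ellipse boundary passes
        # heavy blur destroys the edge, and the boundary gate clears the region
        soft = np.clip(
            ndi.gaussian_filter(img.astype(float), sigma=(9, 9, 0)), 0, 255
        ).astype(np.uint8)
        soft[~roi] = 0
        f3_soft = compute_descriptor("F3", soft, roi)
        assert f3_soft[blood].mean() < f3[blood].mean() * 0.25

    def test_f4_accepts_wider_reds_than_f1(self):
        img, roi = _uniform_field((180, 100, 50))  # orange-red distractor color
        f1 = compute_descriptor("F1", img, roi)
        f4 = compute_descriptor("F4", img, roi)
        assert f4[0, 0] > f1[0, 0]


class TestComputeAll:
    def test_all_black_image_gives_zero_stack(self):
        img = np.zeros(TEST_SHAPE + (3,), dtype=np.uint8)
        roi = np.ones(TEST_SHAPE, dtype=bool)
        assert not compute_all(img, roi).any()

    def test_stack_shape_and_channel_consistency(self, crisp_frame):
        img, _, roi = crisp_frame
        stack = compute_all(img, roi)
        assert stack.shape == TEST_SHAPE + (9,)
        for c, did in enumerate(DESCRIPTOR_IDS):
            np.testing.assert_allclose(
                stack[..., c], compute_descriptor(did, img, roi), atol=1e-12
            )

    def test_blood_frame_channel_pattern(self, crisp_frame):
        img, blood, roi = crisp_frame
        stack = compute_all(img, roi)
        for c in (0, 1, 2):  # F1-F3 light up inside the blood blob
            assert stack[..., c][blood].mean() > 0.3
        assert np.unique(stack[..., 7][roi]).size == 1  # F8 constant over roi

    def test_range_and_masking_invariant(self, frame_battery):
        for img, _, fov in frame_battery:
            stack = compute_all(img, fov)
            assert stack.min() >= 0.0 and stack.max() <= 1.0
            assert not stack[~fov].any()

    def test_parameter_overrides_change_output(self, crisp_frame):
        img, _, roi = crisp_frame
        default = compute_descriptor("F1", img, roi)
        relaxed = compute_descriptor("F1", img, roi, DescriptorParams().replace(f1_r_floor=0))
        assert (relaxed >= default - 1e-12).all()
        with pytest.raises(InvalidInputError):
            DescriptorParams().replace(no_such_param=1)
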