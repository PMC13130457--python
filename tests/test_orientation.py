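"""Orientation pipeline: angle math, each stage, and end-to-end recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberquant import (
    LabelMap,
    bin_angles,
    enhance_tubular,
    make_fiber_frame,
    object_orientation,
    preprocess_frame,
    relative_angle,
    run_orientation_pipeline,
    segment_fiber,
    segment_mitochondria,
)
from fiberquant.core_io import PlaneImage, VolumeImage
from fiberquant.errors import DegenerateInputError, ValidationError

from conftest import frame_to_stack


def brute_force_fold(a: float, b: float) -> float:
    """Independent oracle: smallest angle between two axial directions."""
    best = 360.0
    for turn_a in (a, a + 180.0):
        for turn_b in (b, b + 180.0):
            best = min(best, abs(turn_a - turn_b))
    return best


class TestRelativeAngle:
    def test_matches_brute_force_on_degree_grid(self):
        """Exact agreement with four-way unfolding over all 1-degree pairs."""
        for a in range(0, 180):
            for b in range(0, 180):
                assert relative_angle(float(a), float(b)) == brute_force_fold(a, b)

    @pytest.mark.parametrize(
        "obj,fiber,expected", [(45, 45, 0), (150, 0, 30), (10, 170, 20)]
    )
    def test_documented_examples(self, obj, fiber, expected):
        assert relative_angle(obj, fiber) == expected

    @given(
        a=st.floats(0, 179.999), b=st.floats(0, 179.999)
    )
    @settings(max_examples=300, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        r = relative_angle(a, b)
        assert r == relative_angle(b, a)
        assert 0 <= r <= 90

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            relative_angle(180.0, 0.0)
        with pytest.raises(ValidationError):
            relative_angle(0.0, -1.0)


class TestBinAngles:
    def test_uniform_examples(self):
        s = bin_angles([10, 45, 80])
        assert s.counts == (1, 1, 1)
        np.testing.assert_allclose(s.proportions, (1 / 3, 1 / 3, 1 / 3))

    def test_edge_conventions(self):
        assert bin_angles([30]).counts == (0, 1, 0)   # half-open left edge
        assert bin_angles([60]).counts == (0, 0, 1)
        s = bin_angles([90, 90])                      # 90 closes the last bin
        assert s.proportions[2] == 1.0

    def test_proportions_sum_to_one_on_random_draws(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 90, size=1000)
        s = bin_angles(angles)
        assert sum(s.counts) == 1000
        assert abs(sum(s.proportions) - 1.0) < 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bin_angles([])
        with pytest.raises(ValidationError):
            bin_angles([91.0])


class TestPreprocessFrame:
    def test_constant_image_is_fixed_point(self):
        frame = PlaneImage(np.full((32, 32), 7.0), (0.1, 0.1))
        out = preprocess_frame(frame, 2.0, 0.15)
        np.testing.assert_array_equal(out.pixels, frame.pixels)

    def test_noise_suppressed_edge_preserved(self):
        """On a noisy step edge: flat-region variance drops >= 50% and the
        half-maximum crossing moves by less than one pixel."""
        rng = np.random.default_rng(1)
        img = np.zeros((64, 64))
        img[:, 32:] = 100.0
        noisy = img + rng.normal(0, 10, img.shape)
        out = preprocess_frame(PlaneImage(noisy, (0.1, 0.1)), 2.0, 0.15).pixels
        for sl in (np.s_[:, 4:24], np.s_[:, 40:60]):
            assert out[sl].var() <= 0.5 * noisy[sl].var()
        mid = 0.5 * (out[:, 4:24].mean() + out[:, 40:60].mean())
        crossings = [np.argmax(row >= mid) for row in out]
        assert abs(np.mean(crossings) - 32) < 1.0

    def test_nonpositive_sigma_rejected(self):
        frame = PlaneImage(np.zeros((8, 8)), (0.1, 0.1))
        with pytest.raises(ValidationError):
            preprocess_frame(frame, 0.0, 0.1)
        with pytest.raises(ValidationError):
            preprocess_frame(frame, 1.0, 0.0)


class TestSegmentFiber:
    @pytest.mark.parametrize("angle,tol", [(30.0, 2.0), (0.0, 1.0), (117.0, 2.0)])
    def test_band_angle_recovered(self, angle, tol):
        frame, _ = make_fiber_frame(1, (1, 0, 0), angle, noise_sd=0.0, seed=2)
        est = segment_fiber(preprocess_frame(frame)).angle_deg
        assert min(abs(est - angle), 180 - abs(est - angle)) <= tol

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            segment_fiber(PlaneImage(np.full((32, 32), 3.0), (0.1, 0.1)))


class TestEnhanceTubular:
    def test_blank_gives_zero_response(self):
        out = enhance_tubular(PlaneImage(np.zeros((32, 32)), (0.1, 0.1)), [1, 2])
        assert np.all(out.pixels == 0)

    def test_rod_centerline_response_dominates_background(self):
        img = np.full((64, 64), 10.0)
        img[30:34, 10:54] = 200.0  # rod of radius ~2 px
        v = enhance_tubular(PlaneImage(img, (0.1, 0.1)), [1, 2, 3]).pixels
        centerline = v[31:33, 14:50].mean()
        background = v[5:20, 5:60].mean()
        assert centerline > 5 * max(background, 1e-12)

    def test_response_bounded(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1000, (48, 48))
        v = enhance_tubular(PlaneImage(img, (0.1, 0.1)), [1, 2]).pixels
        assert v.min() >= 0 and v.max() <= 1

    def test_empty_scales_rejected(self):
        with pytest.raises(ValidationError):
            enhance_tubular(PlaneImage(np.zeros((8, 8)), (0.1, 0.1)), [])


class TestSegmentMitochondria:
    def _vesselness_with_rods(self):
        v = np.zeros((80, 80))
        v[10:12, 5:30] = 0.9
        v[40:42, 10:40] = 0.8
        v[60:75, 60:62] = 0.85
        return PlaneImage(v, (0.1, 0.1))

    def test_three_rods_three_labels(self):
        labels = segment_mitochondria(
            self._vesselness_with_rods(), np.ones((80, 80), bool), 10
        )
        assert labels.n_objects == 3

    def test_speckle_removed_by_min_area(self):
        v = np.zeros((40, 40))
        v[10:12, 5:30] = 0.9
        v[30, 35] = 0.95  # 1-px speckle
        labels = segment_mitochondria(
            PlaneImage(v, (0.1, 0.1)), np.ones((40, 40), bool), 10
        )
        assert labels.n_objects == 1

    def test_blank_gives_empty_map(self):
        labels = segment_mitochondria(
            PlaneImage(np.zeros((16, 16)), (0.1, 0.1)), np.ones((16, 16), bool), 5
        )
        assert labels.n_objects == 0

    def test_out_of_range_vesselness_rejected(self):
        with pytest.raises(ValidationError):
            segment_mitochondria(
                PlaneImage(np.full((8, 8), 2.0), (0.1, 0.1)), np.ones((8, 8), bool), 5
            )


class TestObjectOrientation:
    def _rect(self, shape, r0, c0, h, w):
        arr = np.zeros(shape, dtype=np.int32)
        arr[r0:r0 + h, c0:c0 + w] = 1
        return LabelMap(arr)

    def test_horizontal_rectangle(self):
        (label, angle, ecc), = object_orientation(self._rect((30, 40), 10, 5, 3, 20))
        assert min(angle, 180 - angle) <= 0.5
        assert ecc > 0.9

    def test_vertical_rectangle(self):
        (_, angle, _), = object_orientation(self._rect((40, 30), 5, 10, 20, 3))
        assert abs(angle - 90) <= 0.5

    def test_rasterized_45_degree_rod(self):
        arr = np.zeros((40, 40), dtype=np.int32)
        for i in range(25):
            arr[30 - i, 5 + i] = 1
            arr[29 - i, 5 + i] = 1
        (_, angle, _), = object_orientation(LabelMap(arr))
        assert abs(angle - 45) <= 2.0

    def test_empty_map_empty_list(self):
        assert object_orientation(LabelMap(np.zeros((5, 5), np.int32))) == []


class TestPipeline:
    def test_recovers_pure_mixtures(self):
        for fractions, bin_idx in [((1, 0, 0), 0), ((0, 0, 1), 2)]:
            frame, _ = make_fiber_frame(60, fractions, 25.0, seed=8)
            summary, table = run_orientation_pipeline(frame_to_stack(frame))
            assert summary.n_total >= 50
            assert summary.proportions[bin_idx] >= 0.95

    def test_mixed_recovery_within_tolerance(self, small_fiber_fixture):
        frame, truth = small_fiber_fixture
        summary, _ = run_orientation_pipeline(frame_to_stack(frame))
        for est, true in zip(summary.proportions, truth.params["bin_fractions"]):
            assert abs(est - true) < 0.06  # n=120: wider band than the n=1000 check

    def test_blank_stack_flagged_unreliable(self):
        stack = VolumeImage(np.zeros((1, 1, 64, 64)), (1, 0.1, 0.1), ("tomm20",))
        summary, table = run_orientation_pipeline(stack)
        assert not summary.reliable
        assert summary.n_total == 0
        assert table.empty

    def test_anisotropic_pixels_rejected(self):
        stack = VolumeImage(np.zeros((1, 1, 32, 32)), (1, 0.2, 0.1), ("tomm20",))
        with pytest.raises(ValidationError):
            run_orientation_pipeline(stack)

    def test_rotational_equivariance(self):
        """Rotating the scene by 15 degrees leaves the recovered relative
        angles essentially unchanged (the measurement is fiber-relative)."""
        frame_a, _ = make_fiber_frame(100, (0.2, 0.3, 0.5), 20.0, seed=21)
        frame_b, _ = make_fiber_frame(100, (0.2, 0.3, 0.5), 35.0, seed=21)
        sa, ta = run_orientation_pipeline(frame_to_stack(frame_a))
        sb, tb = run_orientation_pipeline(frame_to_stack(frame_b))
        med_a = np.median(ta["relative_angle_deg"])
        med_b = np.median(tb["relative_angle_deg"])
        assert abs(med_a - med_b) < 3.0
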