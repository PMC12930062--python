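import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synaptopy import (
    DetectionParams,
    detect_puncta,
    gen_stack,
    log_response,
    normalize_intensity,
    quality_filter,
    white_tophat,
    wiener_denoise,
)
from synaptopy.simulate import StackGeometry

from conftest import grid, greedy_centroid_match, make_punctum, square_footprint


def gaussian_blob(shape_yx, cy, cx, sigma, amplitude):
    yy, xx = np.mgrid[: shape_yx[0], : shape_yx[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestNormalize:
    def test_constant_grid_maps_to_zero(self):
        g = grid(np.full((2, 16, 16), 7.0))
        out = normalize_intensity(g, 1, 99)
        assert np.all(out.values == 0)

    def test_linear_case_is_exact(self):
        vals = np.arange(101, dtype=float).reshape(1, 1, 101) * np.ones((2, 3, 1))
        out = normalize_intensity(grid(vals), 0, 100)
        np.testing.assert_allclose(out.values, vals / 100.0, atol=1e-12)

    def test_percentile_clipping_matches_direct_computation(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1000, size=(4, 50, 50))
        out = normalize_intensity(grid(vals), 1, 99).values
        q_low, q_high = np.percentile(vals, [1, 99])
        expected = np.clip((vals - q_low) / (q_high - q_low), 0, 1)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        interior = (out > 0) & (out < 1)
        assert interior.mean() >= 0.98
        assert np.any(out == 0) and np.any(out == 1)
        # order statistics preserved
        flat_in, flat_out = vals.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(offset=st.floats(0, 1e4), scale=st.floats(0.01, 100))
    def test_affine_input_invariance(self, offset, scale):
        """Normalization cancels affine intensity changes exactly."""
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 100, size=(2, 20, 20))
        a = normalize_intensity(grid(vals), 2, 98).values
        b = normalize_intensity(grid(vals * scale + offset), 2, 98).values
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestWhiteTophat:
    def test_constant_slice_maps_to_zero(self):
        out = white_tophat(grid(np.full((2, 32, 32), 0.6)), radius=3)
        np.testing.assert_allclose(out.values, 0, atol=1e-12)

    def test_single_pixel_spike_retained(self):
        vals = np.zeros((1, 32, 32))
        vals[0, 16, 16] = 0.8
        out = white_tophat(grid(vals), radius=2)
        assert out.values[0, 16, 16] == pytest.approx(0.8)

    def test_blob_on_ramp_background_removed(self):
        ramp = np.linspace(0, 0.3, 64)[None, :] * np.ones((64, 1))
        blob = gaussian_blob((64, 64), 32, 32, sigma=2, amplitude=0.5)
        vals = (ramp + blob)[None]
        out = white_tophat(grid(vals), radius=8).values[0]
        off_blob = out.copy()
        off_blob[24:41, 24:41] = 0
        assert off_blob.max() < 0.05
        assert out[32, 32] > 0.4

    def test_output_bounded_by_input(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 1, size=(3, 32, 32))
        out = white_tophat(grid(vals), radius=4)
        assert np.all(out.values >= 0)
        assert np.all(out.values <= vals + 1e-12)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            white_tophat(grid(np.ones((1, 8, 8))), radius=10)


class TestWiener:
    def test_constant_grid_unchanged(self):
        g = grid(np.full((2, 16, 16), 0.4))
        out = wiener_denoise(g, window=3)
        np.testing.assert_allclose(out.values, 0.4, atol=1e-12)

    def test_zero_grid_unchanged(self):
        out = wiener_denoise(grid(np.zeros((2, 16, 16))), window=3)
        np.testing.assert_array_equal(out.values, 0)

    def test_reduces_noise_mse_on_blob(self):
        rng = np.random.default_rng(11)
        clean = gaussian_blob((64, 64), 32, 32, sigma=3, amplitude=0.6)[None] + 0.2
        noisy = np.clip(clean + rng.normal(0, 0.05, clean.shape), 0, None)
        out = wiener_denoise(grid(noisy), window=3).values
        assert np.mean((out - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            wiener_denoise(grid(np.ones((1, 8, 8))), window=4)


class TestLogResponse:
    def test_flat_input_zero_response(self):
        out = log_response(grid(np.full((2, 32, 32), 0.3)), sigma=2.0)
        assert np.max(np.abs(out.values)) < 1e-10

    def test_blob_response_peaks_at_center(self):
        vals = gaussian_blob((64, 64), 30, 35, sigma=2, amplitude=1.0)[None]
        resp = log_response(grid(vals), sigma=2.0).values[0]
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 35) <= 1

    def test_two_blobs_two_maxima(self):
        vals = (
            gaussian_blob((64, 64), 32, 20, sigma=2, amplitude=1.0)
            + gaussian_blob((64, 64), 32, 40, sigma=2, amplitude=1.0)
        )[None]
        resp = log_response(grid(vals), sigma=2.0).values[0]
        from scipy.ndimage import maximum_filter

        local_max = (resp == maximum_filter(resp, size=5)) & (resp > resp.max() / 2)
        assert local_max.sum() == 2


class TestQualityFilter:
    def test_permissive_thresholds_are_identity(self):
        puncta = [make_punctum(i, {0: square_footprint(2, 2, s)}) for i, s in enumerate([1, 3, 7])]
        params = DetectionParams(min_voxels=1, max_voxels=10**9, min_mean_intensity=0.0)
        assert quality_filter(puncta, params) == puncta

    def test_size_bounds_applied(self):
        sizes = {2: (1, 2), 5: (1, 5), 40: (5, 8)}  # voxels: 1x2, 1x5, 5x8
        puncta = [
            make_punctum(0, {0: [(y, x) for y in range(1) for x in range(2)]}),
            make_punctum(1, {0: [(y, x) for y in range(1) for x in range(5)]}),
            make_punctum(2, {0: [(y, x) for y in range(5) for x in range(8)]}),
        ]
        assert [p.n_voxels for p in puncta] == [2, 5, 40]
        params = DetectionParams(min_voxels=3, max_voxels=30, min_mean_intensity=0.0)
        kept = quality_filter(puncta, params)
        assert [p.n_voxels for p in kept] == [5]

    def test_min_voxels_above_all_gives_empty(self):
        puncta = [make_punctum(0, {0: square_footprint(0, 0, 3)})]
        params = DetectionParams(min_voxels=100, max_voxels=1000, min_mean_intensity=0.0)
        assert quality_filter(puncta, params) == []

    def test_intensity_floor_applied(self):
        lo = make_punctum(0, {0: square_footprint(0, 0, 6)}, mean_intensity=0.01)
        hi = make_punctum(1, {0: square_footprint(10, 10, 6)}, mean_intensity=0.5)
        params = DetectionParams(min_voxels=1, max_voxels=1000, min_mean_intensity=0.05)
        assert quality_filter([lo, hi], params) == [hi]


class TestDetectPuncta:
    def test_zero_stack_gives_empty_set(self):
        result = detect_puncta(grid(np.zeros((5, 64, 64))))
        assert len(result) == 0

    def test_single_planted_blob_detected_at_truth(self):
        stack, truth = gen_stack(
            n_pre=1, n_post=0, coloc_fraction=0.0, snr=10.0,
            geometry=StackGeometry(nz=9, ny=64, nx=64), seed=21,
        )
        result = detect_puncta(stack.pre, channel_label="pre")
        assert len(result) == 1
        det_vox = np.array(result.puncta[0].centroid_um) / np.array([0.30, 0.06013, 0.06013])
        assert np.linalg.norm(det_vox - truth.centers("pre")[0]) <= 1.0

    def test_determinism(self, small_stack):
        stack, _ = small_stack
        a = detect_puncta(stack.pre)
        b = detect_puncta(stack.pre)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert pa.centroid_um == pb.centroid_um
            assert pa.n_voxels == pb.n_voxels
            np.testing.assert_array_equal(
                np.sort(pa.footprints[pa.z_min], axis=0),
                np.sort(pb.footprints[pb.z_min], axis=0),
            )

    def test_volume_bookkeeping_identity(self, small_stack):
        stack, _ = small_stack
        result = detect_puncta(stack.pre)
        dz, dy, dx = stack.voxel_size
        total_voxels = sum(p.n_voxels for p in result)
        total_volume = sum(p.volume_um3 for p in result)
        assert total_volume == pytest.approx(total_voxels * dz * dy * dx, rel=1e-12)

    def test_z_footprints_contiguous_and_nonempty(self, small_stack):
        stack, _ = small_stack
        for p in detect_puncta(stack.pre):
            zs = sorted(p.footprints)
            assert zs == list(range(zs[0], zs[-1] + 1))
            assert all(len(fp) > 0 for fp in p.footprints.values())

    def test_intensity_offset_invariance(self, small_stack):
        """Adding a constant offset then re-normalizing yields identical detections."""
        stack, _ = small_stack
        shifted = stack.pre.with_values(stack.pre.values + 123.0)
        a = detect_puncta(stack.pre)
        b = detect_puncta(shifted)
        assert len(a) == len(b)
        assert [p.n_voxels for p in a] == [p.n_voxels for p in b]
        np.testing.assert_allclose(
            [p.centroid_um for p in a], [p.centroid_um for p in b], atol=1e-9
        )

    def test_recall_precision_on_small_reference_stack(self, small_stack):
        stack, truth = small_stack
        result = detect_puncta(stack.pre, channel_label="pre")
        matched = greedy_centroid_match(
            [p.centroid_um for p in result], truth.centers("pre")
        )
        assert matched / truth.n_pre >= 0.9
        assert matched / len(result) >= 0.9


class TestDetectionParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p_low": 50, "p_high": 50},
            {"p_low": -1},
            {"wiener_window": 4},
            {"median_window": 2},
            {"log_sigmas": ()},
            {"log_sigmas": (0.0,)},
            {"min_voxels": 0},
            {"min_voxels": 100, "max_voxels": 10},
            {"response_threshold": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionParams(**kwargs)
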