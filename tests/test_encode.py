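"""Motion encoding: crop/split, CoP moments, smoothing, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matmotion as mm
from matmotion.encode import (MotionSignals, area_to_grid, filter_signals,
                              moving_average, normalize)


def brute_force_cop(area):
    """Independent double-loop moment computation (1-based indices)."""
    m, n = area.shape
    total = sx = sy = 0.0
    for i in range(m):
        for j in range(n):
            total += area[i, j]
            sx += (i + 1) * area[i, j]
            sy += (j + 1) * area[i, j]
    return sx / total, sy / total, total / (m * n)


class TestCropAndSplit:
    def test_retains_754_cells(self, rng):
        frame = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        top, bottom = mm.crop_and_split(frame)
        assert top.shape == (12, 26) and bottom.shape == (17, 26)
        assert top.size + bottom.size == 754

    def test_cropped_out_column_vanishes(self):
        frame = np.zeros((32, 32))
        frame[0, 2] = 99.0  # original row 1, column 3 (1-based): outside crop
        top, bottom = mm.crop_and_split(frame)
        assert top.max() == 0 and bottom.max() == 0

    def test_area_sums_of_all_ones(self):
        top, bottom = mm.crop_and_split(np.ones((32, 32)))
        assert top.sum() == 312 and bottom.sum() == 442

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="32x32"):
            mm.crop_and_split(np.zeros((31, 32)))


class TestComputeCop:
    def test_point_mass(self):
        area = np.zeros((12, 26))
        area[4, 6] = 10.0  # 1-based (5, 7)
        x, y, p = mm.compute_cop(area)
        assert (x, y) == (5.0, 7.0)
        assert p == pytest.approx(10.0 / 312)

    def test_uniform_area_centred(self):
        x, y, p = mm.compute_cop(np.full((17, 26), 3.5))
        assert x == pytest.approx(9.0)  # (17+1)/2
        assert y == pytest.approx(13.5)
        assert p == pytest.approx(3.5)

    def test_matches_brute_force_on_random_areas(self, rng):
        for _ in range(50):
            area = rng.random((12, 26)) * 255
            got = mm.compute_cop(area)
            want = brute_force_cop(area)
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_zero_area_degenerates_to_centre(self):
        x, y, p = mm.compute_cop(np.zeros((12, 26)))
        assert (x, y, p) == (6.5, 13.5, 0.0)


class TestMovingAverage:
    def test_constant_unchanged(self):
        series = np.full(500, 3.2)
        np.testing.assert_allclose(moving_average(series), series)

    def test_impulse_spreads_to_five_fifths(self):
        series = np.zeros(500)
        series[250] = 1.0
        out = moving_average(series)
        np.testing.assert_allclose(out[248:253], 0.2)
        assert out[247] == out[253] == 0.0

    def test_matches_naive_loop_at_interior(self, rng):
        series = rng.normal(size=100)
        out = moving_average(series)
        for t in range(2, 98):
            assert out[t] == pytest.approx(series[t - 2:t + 3].mean())

    def test_truncated_edges(self, rng):
        series = rng.normal(size=50)
        out = moving_average(series)
        assert out[0] == pytest.approx(series[:3].mean())
        assert out[-1] == pytest.approx(series[-3:].mean())

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            moving_average(np.zeros(10), window=4)
        with pytest.raises(ValueError):
            moving_average(np.zeros(3), window=5)


def random_signals(rng, scale=5.0):
    arr = rng.normal(size=(500, 6)) * scale + rng.normal(size=6)
    return MotionSignals.from_array(arr, stage="filtered")


class TestNormalize:
    def test_constant_signals_all_zero(self):
        sig = MotionSignals.from_array(np.full((500, 6), 2.0), "filtered")
        out = normalize(sig)
        assert out.stage == "normalised"
        assert np.all(out.as_array() == 0.0)

    def test_widest_position_signal_spans_unit_interval(self, rng):
        arr = rng.random((500, 6))
        arr[:, 0] = np.linspace(2, 10, 500)  # x_t range 8 beats all others
        out = normalize(MotionSignals.from_array(arr, "filtered"))
        assert out.x_t.min() == pytest.approx(0.0)
        assert out.x_t.max() == pytest.approx(1.0)

    def test_group_maxima_and_bounds(self, rng):
        for _ in range(100):
            out = normalize(random_signals(rng))
            arr = out.as_array()
            assert arr.min() >= 0.0 and arr.max() <= 1.0
            pos = np.concatenate([out.x_t, out.y_t, out.x_b, out.y_b])
            prs = np.concatenate([out.p_t, out.p_b])
            assert pos.max() == pytest.approx(1.0)
            assert prs.max() == pytest.approx(1.0)
            # every signal is min-subtracted
            for s in (out.x_t, out.y_t, out.p_t, out.x_b, out.y_b, out.p_b):
                assert s.min() == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_bounds_hold_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        arr = normalize(random_signals(rng, scale=rng.uniform(0.01, 100))).as_array()
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestEncodeSnippet:
    def test_output_is_500_by_6_in_unit_interval(self, small_cohort):
        _, snippets, _ = small_cohort
        sig = mm.encode_snippet(snippets[0].frames)
        arr = sig.as_array()
        assert arr.shape == (500, 6)
        assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_static_snippet_encodes_to_zero(self):
        law = mm.MotionLaw(disp_amp=0.0, pressure_amp=0.0, drift_amp=0.0,
                           noise_sd=0.0)
        snippet, _ = mm.generate_snippet(mm.BodyModel(), law, "FMminus", seed=1)
        filtered = mm.encode_snippet(snippet.frames, stage="filtered")
        assert np.ptp(filtered.as_array(), axis=0) == pytest.approx(0.0)
        assert np.all(mm.encode_snippet(snippet.frames).as_array() == 0.0)

    def test_tracks_ground_truth_trajectory(self, quiet_body):
        """Pre-normalisation CoP follows the generator's exact top-blob
        motion within half a grid cell at every time step."""
        law = mm.MotionLaw(disp_amp=2.0, drift_amp=0.2, noise_sd=0.0)
        snippet, traj = mm.generate_snippet(quiet_body, law, "FMminus", seed=21)
        raw = mm.encode_snippet(snippet.frames, stage="raw")
        row, col = area_to_grid(raw.x_t, raw.y_t, "top")
        assert np.max(np.abs(row - traj["top"][:, 0])) < 0.5
        assert np.max(np.abs(col - traj["top"][:, 1])) < 0.5

    def test_scale_invariance(self, quiet_body):
        """Multiplying every frame by k > 0 (infant weight) leaves all
        normalised signals unchanged: the shared denominators divide k out."""
        law = mm.MotionLaw(noise_sd=0.0)
        snippet, _ = mm.generate_snippet(quiet_body, law, "FMplus", seed=4)
        frames = snippet.frames.astype(float)
        a = mm.encode_snippet(frames).as_array()
        b = mm.encode_snippet(frames * 3.7).as_array()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_translation_covariance(self, quiet_body):
        """Shifting a noise-free blob down one row shifts raw x by one."""
        law = mm.MotionLaw(disp_amp=0.5, drift_amp=0.0, noise_sd=0.0)
        s0, _ = mm.generate_snippet(quiet_body, law, "x", seed=6)
        body2 = mm.BodyModel(
            top_center=(quiet_body.top_center[0] + 1, quiet_body.top_center[1]),
            bottom_center=quiet_body.bottom_center,
            blob_sd_top=quiet_body.blob_sd_top,
            blob_sd_bottom=quiet_body.blob_sd_bottom)
        s1, _ = mm.generate_snippet(body2, law, "x", seed=6)
        r0 = mm.encode_snippet(s0.frames, stage="raw")
        r1 = mm.encode_snippet(s1.frames, stage="raw")
        shift = r1.x_t - r0.x_t
        assert np.allclose(shift, 1.0, atol=0.1)  # quantisation error only

    def test_pipeline_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            mm.encode_snippet(np.zeros((500, 31, 32)))
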