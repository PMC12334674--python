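"""Unit and property tests for the two-photon dF/F pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from noradscope.twop import (
    AnalysisWindows,
    Recording4D,
    classify_response,
    compute_dff,
    grand_average,
    long_mode_dff,
    project_z,
    response_fractions,
    rigid_correct,
    roi_traces,
    tile_grid,
    window_response,
)

SHORT_WIN = AnalysisWindows(drop_first=2, baseline=(2, 4), response=(6, 7), stim_frame=5)


def _tiny_movie(rng, t=8, h=6, w=6, lo=50.0, hi=150.0):
    return rng.uniform(lo, hi, (t, h, w))


class TestProjectZ:
    def test_all_ones_sums_to_z(self):
        stack = np.ones((4, 3, 5, 5))
        assert np.array_equal(project_z(stack), np.full((4, 5, 5), 3.0))

    def test_single_slice_identity(self, rng):
        stack = rng.uniform(0, 1, (4, 1, 5, 5))
        assert np.array_equal(project_z(stack), stack[:, 0])

    def test_matches_explicit_loop(self, rng):
        stack = rng.uniform(0, 10, (3, 4, 6, 7))
        out = project_z(stack)
        for t in range(3):
            for y in range(6):
                for x in range(7):
                    assert out[t, y, x] == pytest.approx(sum(stack[t, :, y, x]))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            project_z(np.empty((0, 0, 0, 0)))

    def test_accepts_recording(self, rng):
        rec = Recording4D(rng.uniform(1, 2, (4, 2, 5, 5)), 1.13, 2, 0.22)
        assert project_z(rec).shape == (4, 5, 5)


class TestRigidCorrect:
    def test_motionless_movie_zero_shifts(self, rng):
        frame = rng.uniform(0, 100, (32, 32))
        movie = np.tile(frame, (5, 1, 1))
        _, shifts = rigid_correct(movie, max_shift=3)
        assert shifts == [(0, 0)] * 5

    def test_recovers_planted_shift(self, rng):
        base = rng.uniform(0, 100, (48, 48))
        movie = np.stack([base] * 8)
        movie[5] = np.roll(np.roll(base, -2, axis=0), 1, axis=1)
        corrected, shifts = rigid_correct(movie, max_shift=4)
        # the displaced frame needs (dy, dx) = (2, -1) to return to the template
        assert shifts[5] == (2, -1)
        assert all(s == (0, 0) for i, s in enumerate(shifts) if i != 5)
        inner = np.s_[4:-4, 4:-4]
        np.testing.assert_allclose(corrected[5][inner], base[inner])

    def test_max_shift_zero_is_identity(self, rng):
        movie = rng.uniform(0, 1, (4, 8, 8))
        out, shifts = rigid_correct(movie, max_shift=0)
        assert np.array_equal(out, movie)
        assert shifts == [(0, 0)] * 4


class TestComputeDff:
    def test_arithmetic(self):
        movie = np.full((8, 2, 2), 100.0)
        movie[5] = 110.0
        dff = compute_dff(movie, SHORT_WIN)
        assert dff.data[5] == pytest.approx(0.10)

    def test_constant_movie_is_zero(self):
        movie = np.full((10, 4, 4), 37.0)
        dff = compute_dff(movie, SHORT_WIN)
        assert np.all(dff.data == 0.0)

    def test_matches_loop_oracle(self, rng):
        movie = _tiny_movie(rng)
        dff = compute_dff(movie, SHORT_WIN)
        b0, b1 = SHORT_WIN.baseline
        for y in range(6):
            for x in range(6):
                f0 = np.mean([movie[t, y, x] for t in range(b0 - 1, b1)])
                for t in range(8):
                    expect = (movie[t, y, x] - f0) / f0
                    assert dff.data[t, y, x] == pytest.approx(expect)

    def test_scaling_invariance(self, rng):
        movie = _tiny_movie(rng)
        a = compute_dff(movie, SHORT_WIN)
        b = compute_dff(3.7 * movie, SHORT_WIN)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_dark_pixels_flagged_and_nan(self, rng):
        movie = _tiny_movie(rng)
        movie[:, 0, 0] = 0.0
        dff = compute_dff(movie, SHORT_WIN)
        assert dff.excluded_pixels[0, 0]
        assert dff.n_excluded == 1
        assert np.isnan(dff.data[:, 0, 0]).all()

    def test_onset_frames_flagged_invalid(self, rng):
        dff = compute_dff(_tiny_movie(rng), SHORT_WIN)
        assert not dff.valid_frames[:2].any()
        assert dff.valid_frames[2:].all()

    def test_baseline_beyond_movie_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_dff(_tiny_movie(rng, t=3), SHORT_WIN)

    def test_frame_mean_mode(self, rng):
        movie = _tiny_movie(rng)
        dff = compute_dff(movie, SHORT_WIN, normalization="frame_mean")
        f0 = movie[SHORT_WIN.baseline_slice].mean()
        np.testing.assert_allclose(dff.data, (movie - f0) / f0)

    def test_long_mode_matches_alternate_baseline(self, rng):
        movie = rng.uniform(50, 150, (320, 4, 4))
        a = long_mode_dff(movie, baseline=(20, 300))
        win = AnalysisWindows(baseline=(20, 300), stim_frame=301, response=(302, 302))
        b = compute_dff(movie, win)
        np.testing.assert_array_equal(a.data, b.data)


class TestTileGrid:
    def test_even_partition(self):
        grid = tile_grid(12, 12)
        assert grid.n_tiles == 36
        assert all(y1 - y0 == 2 and x1 - x0 == 2 for y0, y1, x0, x1 in grid.tile_bounds)

    def test_default_fov_partition(self):
        grid = tile_grid(120, 120)
        assert grid.n_tiles == 36
        assert all(
            y1 - y0 == 20 and x1 - x0 == 20 for y0, y1, x0, x1 in grid.tile_bounds
        )

    def test_remainder_goes_to_first_tiles(self):
        grid = tile_grid(13, 12)
        heights = [grid.tile_bounds[r * 6][1] - grid.tile_bounds[r * 6][0] for r in range(6)]
        assert heights == [3, 2, 2, 2, 2, 2]
        cover = np.zeros((13, 12), int)
        for i in range(grid.n_tiles):
            ys, xs = grid.tile_slices(i)
            cover[ys, xs] += 1
        assert np.all(cover == 1)

    def test_rejects_grid_larger_than_image(self):
        with pytest.raises(ValueError):
            tile_grid(5, 10, rows=6, cols=6)

    @given(
        h=st.integers(6, 60),
        w=st.integers(6, 60),
        rows=st.integers(1, 6),
        cols=st.integers(1, 6),
    )
    def test_partition_property(self, h, w, rows, cols):
        grid = tile_grid(h, w, rows, cols)
        cover = np.zeros((h, w), int)
        for i in range(grid.n_tiles):
            ys, xs = grid.tile_slices(i)
            cover[ys, xs] += 1
        assert np.all(cover == 1)


class TestResponseStatistic:
    def test_three_frame_mean(self):
        trace = np.zeros(100)
        trace[88:91] = [0.03, 0.04, 0.05]
        assert window_response(trace, AnalysisWindows()) == pytest.approx(0.04)

    def test_constant_trace(self):
        assert window_response(np.full(100, 0.7), AnalysisWindows()) == pytest.approx(0.7)

    def test_matches_explicit_sum(self, rng):
        trace = rng.normal(0, 1, 120)
        win = AnalysisWindows()
        expect = (trace[88] + trace[89] + trace[90]) / 3
        assert window_response(trace, win) == pytest.approx(expect)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            window_response(np.zeros(50), AnalysisWindows())

    @pytest.mark.parametrize(
        "stat,sd,expected",
        [(0.3, 0.1, "increase"), (-0.3, 0.1, "decrease"), (0.05, 0.1, "none")],
    )
    def test_classification(self, stat, sd, expected):
        assert classify_response(stat, sd) == expected

    def test_classification_threshold_configurable(self):
        assert classify_response(0.25, 0.1, k=2) == "increase"
        assert classify_response(0.25, 0.1, k=3) == "none"


class TestResponseFractions:
    def test_wildtype_like_fraction(self):
        labels = ["increase"] * 27 + ["none"] * 9
        inc, dec, none = response_fractions(labels)
        assert inc == pytest.approx(75.0)
        assert dec == 0.0

    def test_all_none(self):
        assert response_fractions(["none"] * 7) == (0.0, 0.0, 100.0)

    def test_counting_oracle(self, rng):
        labels = list(rng.choice(["increase", "decrease", "none"], size=57))
        inc, dec, none = response_fractions(labels)
        assert inc == pytest.approx(100 * labels.count("increase") / 57)
        assert dec == pytest.approx(100 * labels.count("decrease") / 57)

    @given(st.lists(st.sampled_from(["increase", "decrease", "none"]), min_size=1))
    def test_fractions_sum_to_100(self, labels):
        assert sum(response_fractions(labels)) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            response_fractions([])


def _trace_set(traces, brightness):
    from noradscope.twop import RoiTraceSet, tile_grid

    traces = np.asarray(traces, float)
    n = traces.shape[0]
    return RoiTraceSet(
        traces=traces,
        baseline_brightness=np.asarray(brightness, float),
        baseline_sd=np.zeros(n),
        response_stat=traces.mean(axis=1),
        labels=["none"] * n,
        grid=tile_grid(6, 6, 1, 1),
        windows=SHORT_WIN,
    )


class TestGrandAverage:
    def test_identical_traces_pass_through(self):
        trace = np.linspace(0, 1, 10)
        sets = [_trace_set([trace] * 4, [1, 2, 3, 4]) for _ in range(3)]
        np.testing.assert_allclose(grand_average(sets), trace)

    def test_single_fov_constant_traces(self):
        s = _trace_set([np.full(5, 1.0), np.full(5, 2.0), np.full(5, 3.0)], [5, 5, 5])
        np.testing.assert_allclose(grand_average([s]), np.full(5, 2.0))

    def test_matches_sort_select_average_oracle(self, rng):
        sets = []
        for _ in range(3):
            traces = rng.normal(0, 1, (8, 12))
            bright = rng.uniform(0, 100, 8)
            sets.append(_trace_set(traces, bright))
        expect = np.mean(
            [
                s.traces[np.argsort(-s.baseline_brightness, kind="stable")[:3]].mean(0)
                for s in sets
            ],
            axis=0,
        )
        np.testing.assert_allclose(grand_average(sets), expect)

    def test_brightness_ties_broken_by_index(self):
        traces = np.arange(4 * 3, dtype=float).reshape(4, 3)
        s = _trace_set(traces, [7, 7, 7, 7])
        np.testing.assert_allclose(grand_average([s]), traces[:3].mean(axis=0))

    def test_too_few_rois_rejected(self):
        s = _trace_set(np.zeros((2, 4)), [1, 2])
        with pytest.raises(ValueError):
            grand_average([s])


class TestRoiTraces:
    def _setup(self, rng, t=8, h=6, w=6):
        movie = _tiny_movie(rng, t, h, w)
        dff = compute_dff(movie, SHORT_WIN)
        grid = tile_grid(h, w, 2, 2)
        return movie, dff, grid

    def test_zero_dff_gives_zero_traces(self):
        movie = np.full((8, 6, 6), 50.0)
        dff = compute_dff(movie, SHORT_WIN)
        grid = tile_grid(6, 6, 2, 2)
        out = roi_traces(dff, movie, grid, SHORT_WIN)
        assert np.all(out.traces == 0.0)
        assert np.all(out.response_stat == 0.0)

    def test_uniform_window_value(self):
        movie = np.full((8, 6, 6), 100.0)
        movie[5:7] = 104.0  # response frames 6-7 at dF/F = 0.04
        dff = compute_dff(movie, SHORT_WIN)
        out = roi_traces(dff, movie, tile_grid(6, 6, 2, 2), SHORT_WIN)
        assert np.allclose(out.response_stat, 0.04)

    def test_traces_match_loop_oracle(self, rng):
        movie, dff, grid = self._setup(rng)
        out = roi_traces(dff, movie, grid, SHORT_WIN)
        for i in range(grid.n_tiles):
            ys, xs = grid.tile_slices(i)
            for t in range(8):
                assert out.traces[i, t] == pytest.approx(dff.data[t, ys, xs].mean())

    def test_labels_consistent_with_classifier(self, rng):
        movie, dff, grid = self._setup(rng)
        out = roi_traces(dff, movie, grid, SHORT_WIN, k=2.0)
        for i in range(grid.n_tiles):
            assert out.labels[i] == classify_response(
                out.response_stat[i], out.baseline_sd[i], k=2.0
            )

    def test_shape_mismatch_rejected(self, rng):
        movie, dff, _ = self._setup(rng)
        with pytest.raises(ValueError):
            roi_traces(dff, movie, tile_grid(8, 8, 2, 2), SHORT_WIN)

    def test_pipeline_linearity_in_labels(self, rng):
        movie, _, grid = self._setup(rng)
        out1 = roi_traces(compute_dff(movie, SHORT_WIN), movie, grid, SHORT_WIN)
        scaled = 5.0 * movie
        out2 = roi_traces(compute_dff(scaled, SHORT_WIN), scaled, grid, SHORT_WIN)
        np.testing.assert_allclose(out1.traces, out2.traces, atol=1e-12)
        np.testing.assert_allclose(out1.response_stat, out2.response_stat, atol=1e-12)
        assert out1.labels == out2.labels


class TestPlantAndRecover:
    def test_planted_labels_recovered(self, wt_cohort, wt_analysis):
        """Classification recovers >= 95% of planted ROI classes on the
        control-like cohort (amplitudes are 8x the noise sd)."""
        _, truth = wt_cohort
        sets, _ = wt_analysis
        predicted = [lab for s in sets for lab in s.labels]
        agreement = np.mean(np.asarray(predicted) == truth.roi_labels["label"].to_numpy())
        assert agreement >= 0.95


class TestAnalysisWindows:
    def test_baseline_must_precede_stimulus(self):
        with pytest.raises(ValueError):
            AnalysisWindows(baseline=(20, 70), stim_frame=68)

    def test_response_must_follow_stimulus(self):
        with pytest.raises(ValueError):
            AnalysisWindows(response=(60, 62), stim_frame=68)
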