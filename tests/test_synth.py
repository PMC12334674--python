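"""Tests of the synthetic-data generators and their ground truth."""

import numpy as np
import pandas as pd
import pytest

from noradscope import SimPreset, get_preset
from noradscope._sampling import stratified_lognormal, stratified_normal
from noradscope.synth import (
    gen_behavior_session,
    gen_coloc_volumes,
    gen_fiber_image,
    gen_latencies,
    gen_phago_series,
    gen_twop_cohort,
)
from noradscope.twop import project_z

TINY_TWOP = dict(
    n_animals=1,
    n_fovs=1,
    n_frames=92,
    height=24,
    width=24,
    n_z=2,
    stim_frame=68,
    frame_rate_hz=1.13,
    pixel_size_um=0.22,
    amp_inc=0.04,
    amp_dec=-0.04,
    noise_sd=0.005,
    vessel_tiles=0,
    grid_rows=2,
    grid_cols=2,
    p_inc=0.5,
    p_dec=0.25,
)


def tiny_preset(**overrides):
    seed = overrides.pop("seed", 7)
    return SimPreset("tiny", {**TINY_TWOP, **overrides}, seed=seed)


class TestTwopGenerator:
    def test_zero_amplitude_zero_noise_is_time_constant(self):
        recs, _ = gen_twop_cohort(
            tiny_preset(amp_inc=0.0, amp_dec=0.0, noise_sd=0.0)
        )
        movie = project_z(recs[0])
        assert np.allclose(movie, movie[0])

    def test_forced_increase_labels(self):
        _, gt = gen_twop_cohort(tiny_preset(p_inc=1.0, p_dec=0.0))
        assert set(gt.roi_labels["label"]) == {"increase"}

    def test_same_seed_identical_output(self):
        a, _ = gen_twop_cohort(tiny_preset(p_inc=0.5, p_dec=0.25))
        b, _ = gen_twop_cohort(tiny_preset(p_inc=0.5, p_dec=0.25))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.data, rb.data)

    def test_label_counts_sum_to_total(self):
        _, gt = gen_twop_cohort(tiny_preset(p_inc=0.5, p_dec=0.25))
        counts = gt.roi_labels["label"].value_counts()
        assert counts.sum() == 4  # 2x2 grid, one FOV

    def test_baseline_strictly_positive(self):
        recs, _ = gen_twop_cohort(tiny_preset(noise_sd=0.0, p_inc=0.0, p_dec=0.0))
        assert (project_z(recs[0]) > 0).all()

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="response-window end"):
            gen_twop_cohort(tiny_preset(n_frames=90))

    def test_invalid_class_probabilities_rejected(self):
        with pytest.raises(ValueError):
            gen_twop_cohort(tiny_preset(p_inc=0.8, p_dec=0.4))


class TestFiberGenerator:
    def test_zero_fraction_empty_mask(self):
        img, mask = gen_fiber_image(0.0, noise_sd=0.0, seed=0)
        assert not mask.any()
        assert np.all(img.pixels == img.pixels.flat[0])

    def test_planted_fraction_within_tolerance(self):
        _, mask = gen_fiber_image(12.0, noise_sd=0.0, seed=3)
        assert 10.5 <= 100 * mask.mean() <= 13.5

    def test_two_seeds_same_fraction_different_layout(self):
        _, m1 = gen_fiber_image(12.0, seed=1)
        _, m2 = gen_fiber_image(12.0, seed=2)
        assert abs(100 * m1.mean() - 100 * m2.mean()) <= 3.0
        assert not np.array_equal(m1, m2)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            gen_fiber_image(75.0)

    def test_image_nonnegative_with_noise(self):
        img, _ = gen_fiber_image(10.0, noise_sd=30.0, seed=0)
        assert (img.pixels >= 0).all()


class TestVolumeGenerator:
    def test_truth_matches_brute_force_recount(self):
        channels, gt = gen_coloc_volumes(seed=11)
        voxvol = channels.voxel_volume_um3
        for markers, vol in gt.true_intersections.items():
            inter = np.ones_like(channels.masks["net"])
            for m in markers:
                inter = inter & channels.masks[m]
            assert vol == pytest.approx(int(inter.sum()) * voxvol)

    def test_intersections_bounded_by_parents(self):
        channels, gt = gen_coloc_volumes(seed=11)
        for markers, vol in gt.true_intersections.items():
            assert vol <= min(channels.volume_um3(m) for m in markers) + 1e-9

    def test_nested_larger_than_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            gen_coloc_volumes({"lysosome_radius_um": 10.0, "cell_radius_um": 2.0})

    def test_deterministic(self):
        a, _ = gen_coloc_volumes(seed=4)
        b, _ = gen_coloc_volumes(seed=4)
        for k in a.masks:
            np.testing.assert_array_equal(a.masks[k], b.masks[k])


class TestBehaviorGenerator:
    def test_views_are_exact_projections(self):
        top, side, gt = gen_behavior_session(duration_s=5, fps=20, seed=1)
        np.testing.assert_allclose(top["x"], gt.true_traj[:, 0])
        np.testing.assert_allclose(top["y"], gt.true_traj[:, 1])
        np.testing.assert_allclose(side["z"], gt.true_traj[:, 2])

    def test_stationary_nose_at_tip(self):
        tip = (10.0, 10.0, 5.0)
        _, _, gt = gen_behavior_session(
            duration_s=2, fps=10, tip=tip, step_sd_cm=0.0, start=tip, seed=0
        )
        dist = np.linalg.norm(gt.true_traj - np.asarray(tip), axis=1)
        assert np.all(dist == 0.0)

    def test_attraction_pulls_toward_tip(self):
        tip = (10.0, 10.0, 5.0)
        _, _, free = gen_behavior_session(0.0, duration_s=30, fps=10, tip=tip, seed=9)
        _, _, drawn = gen_behavior_session(3.0, duration_s=30, fps=10, tip=tip, seed=9)
        d_free = np.linalg.norm(free.true_traj - np.asarray(tip), axis=1).mean()
        d_drawn = np.linalg.norm(drawn.true_traj - np.asarray(tip), axis=1).mean()
        assert d_drawn < d_free

    def test_trajectory_stays_in_box(self):
        _, _, gt = gen_behavior_session(0.0, duration_s=30, fps=10, seed=2)
        assert (gt.true_traj >= 0).all() and (gt.true_traj <= 20).all()


class TestLatencyGenerator:
    def test_cv_zero_gives_exact_means(self):
        df, _ = gen_latencies(mean_control=40, ratio=1.6, cv=0.0, seed=0)
        ctrl = df.loc[df["group"] == "control", "latency_s"]
        case = df.loc[df["group"] == "case", "latency_s"]
        assert np.allclose(ctrl, 40.0)
        assert np.allclose(case, 64.0)

    def test_ratio_one_contrast_vanishes_at_large_n(self):
        df, _ = gen_latencies(ratio=1.0, n_control=10_000, n_case=10_000, seed=5)
        means = df.groupby("group")["latency_s"].mean()
        pct = 100 * (means["case"] - means["control"]) / means["control"]
        assert abs(pct) < 1.0

    def test_same_seed_reproducible(self):
        a, _ = gen_latencies(seed=3)
        b, _ = gen_latencies(seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_group_params_record_planted_ratio(self):
        _, gt = gen_latencies(mean_control=40, ratio=1.6, seed=0)
        assert gt.group_params["mean_case"] / gt.group_params["mean_control"] == pytest.approx(1.6)


class TestPhagoGenerator:
    def test_noise_free_ratio_is_exact(self):
        df, _ = gen_phago_series(fold=1.33, noise_cv=0.0, seed=0)
        from noradscope.assay import normalize_to_control

        folds = {f.group: f.fold for f in normalize_to_control(df, "control", 12.0)}
        assert folds["case"] == pytest.approx(1.33)

    def test_cytod_group_near_zero(self):
        df, _ = gen_phago_series(include_cytod=True, seed=0)
        cyto = df.loc[df["group"] == "cytoD", "total_intensity"]
        assert np.allclose(cyto, 0.0)

    @pytest.mark.parametrize("seed", [10, 11, 12, 13, 14])
    def test_recovered_fold_within_tolerance(self, seed):
        from noradscope.assay import normalize_to_control

        df, _ = gen_phago_series(fold=1.33, noise_cv=0.10, n_wells=12, seed=seed)
        folds = {f.group: f.fold for f in normalize_to_control(df, "control", 12.0)}
        assert folds["case"] == pytest.approx(1.33, abs=0.05)

    def test_missing_reference_time_rejected(self):
        with pytest.raises(ValueError, match="12"):
            gen_phago_series(timepoints=(0, 6, 24))


class TestStratifiedSampling:
    def test_normal_mean_close(self, rng):
        x = stratified_normal(rng, 20, 12.0, 1.0)
        assert x.mean() == pytest.approx(12.0, abs=0.2)

    def test_lognormal_mean_close(self, rng):
        x = stratified_lognormal(rng, 18, 64.0, 0.3)
        assert x.mean() == pytest.approx(64.0, rel=0.05)

    def test_zero_spread_constant(self, rng):
        assert np.allclose(stratified_normal(rng, 5, 3.0, 0.0), 3.0)
        assert np.allclose(stratified_lognormal(rng, 5, 3.0, 0.0), 3.0)


class TestPresets:
    def test_known_presets_resolve(self):
        for name in ["wt_fig2", "app_fig2", "fiberloss_2m", "dbh_app", "buriedfood_3m", "phago_12h"]:
            assert get_preset(name).name == name

    def test_seed_override(self):
        assert get_preset("wt_fig2", 7).seed == 7
        assert get_preset("wt_fig2").seed == 42

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("nope")
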