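"""Cohort generator: heterogeneity draws, timelines, rendering, determinism."""

import numpy as np
import pandas as pd
import pytest

from avoshelf.synthetic_orchard import (GROUP_PRESETS, CohortConfig, FruitParams,
                                        RenderConfig, StorageGroup, calibrated_dwell10,
                                        fruit_mask, render_fruit_image,
                                        sample_fruit_params, simulate_cohort,
                                        stage_timeline)

UNIT_GROUP = StorageGroup("T20", alpha5=-2.0, alpha9=-1.0, temperature_mean_c=20.0)
NOISELESS = CohortConfig(group_sizes={"T20": 1}, speed_sd=0.0, dwell_cv=0.0,
                         start_probs=(1.0, 0.0, 0.0), blemish_prob=0.0)


class TestFruitParams:
    def test_zero_jitter_gives_unit_speed(self):
        p = sample_fruit_params("T20", 7, cfg=NOISELESS)
        assert p.speed_factor == 1.0

    def test_same_seed_reproduces_params(self):
        a = sample_fruit_params("T10", 42)
        b = sample_fruit_params("T10", 42)
        assert a == b

    def test_log_speed_centered(self):
        # lognormal with median 1: mean log speed ~ 0 (law of large numbers)
        rng = np.random.default_rng(3)
        cfg = CohortConfig(speed_sd=0.2)
        logs = np.log([sample_fruit_params("T20", rng, cfg=cfg).speed_factor
                       for _ in range(10_000)])
        assert abs(logs.mean()) < 3 * 0.2 / np.sqrt(len(logs))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown storage group"):
            sample_fruit_params("T15", 0)

    def test_blemish_on_at_most_one_side(self):
        rng = np.random.default_rng(5)
        cfg = CohortConfig(blemish_prob=1.0)
        sides = {sample_fruit_params("T20", rng, cfg=cfg).blemish_side for _ in range(50)}
        assert sides <= {"front", "back"}


class TestStorageGroupPresets:
    @pytest.mark.parametrize("name", ["T10", "T20", "Tamb"])
    def test_slope_presets_negative_and_paired(self, name):
        g = GROUP_PRESETS[name]
        assert g.alpha5 < 0 and g.alpha9 < 0
        assert abs(abs(g.alpha5) / (2 * abs(g.alpha9)) - 1) <= 0.10

    def test_mispaired_slopes_rejected(self):
        with pytest.raises(ValueError, match="2"):
            StorageGroup("T10", alpha5=-5.0, alpha9=-2.0, temperature_mean_c=10.0)


class TestStageTimeline:
    def test_unit_dwell_advances_one_stage_per_day(self):
        p = FruitParams(1, UNIT_GROUP, speed_factor=1.0, start_stage10=1,
                        blemish_side="none", blemish_intensity=0.0)
        t = stage_timeline(p, rng=0, cfg=NOISELESS)
        # stage s on day s-1; first stage-9 day is day 8
        assert list(t.stage_by_day) == list(range(1, 11))
        assert t.endpoint_day9 == 8
        assert t.days_left9(t.endpoint_day9) == 0.0

    def test_stages_monotone_and_in_range(self, small_cohort):
        _, trajectories, _ = small_cohort
        for t in trajectories:
            s = t.stage_by_day
            assert np.all(np.diff(s) >= 0)
            assert s.min() >= 1 and s.max() <= 10
            if t.endpoint_day9 is not None and t.end_day10 is not None:
                assert t.endpoint_day9 <= t.end_day10

    def test_endpoint_ratio_tracks_preset_slopes(self):
        # T10 fruits take ~|alpha9(T10)|/|alpha9(T20)| ~ 2.07x longer to ripen
        means = {}
        for gname in ("T10", "T20"):
            cfg = CohortConfig(group_sizes={gname: 500})
            traj, _ = simulate_cohort(cfg, 11)
            means[gname] = np.mean([t.endpoint_day9 for t in traj
                                    if t.endpoint_day9 is not None])
        expected = abs(GROUP_PRESETS["T10"].alpha9 / GROUP_PRESETS["T20"].alpha9)
        assert means["T10"] / means["T20"] == pytest.approx(expected, rel=0.10)

    def test_censoring_under_observation_cap(self):
        cfg = CohortConfig(group_sizes={"T10": 1}, max_days=3, speed_sd=0.0,
                           dwell_cv=0.0, start_probs=(1.0, 0.0, 0.0), blemish_prob=0.0)
        p = sample_fruit_params("T10", 0, cfg=cfg)
        t = stage_timeline(p, rng=0, cfg=cfg)
        assert t.censored and t.endpoint_day9 is None
        assert t.n_days == 4

    def test_calibrated_dwell_identity_at_unit_slope(self):
        cfg = CohortConfig(speed_sd=0.0, dwell_cv=0.0, start_probs=(1.0, 0.0, 0.0))
        assert calibrated_dwell10(-1.0, 10, cfg) == pytest.approx(1.0, abs=1e-12)


class TestRendering:
    def _flat_cfg(self, **kw):
        return RenderConfig(image_size=48, noise_sd=0.0,
                            patch_density_by_stage=(0.0,) * 10, mold_spot_rate=0.0, **kw)

    def _traj(self):
        p = FruitParams(1, UNIT_GROUP, 1.0, 1, "none", 0.0)
        return stage_timeline(p, rng=0, cfg=NOISELESS)

    def test_flat_render_is_constant_anchor_color(self):
        from skimage import color as skcolor

        cfg = self._flat_cfg()
        t = self._traj()
        img, rec = render_fruit_image(t, day=2, side="front", cfg=cfg, rng_seed=0)
        assert rec["ri10"] == 3
        mask = fruit_mask(cfg)
        fruit = img[mask]
        assert (fruit == fruit[0]).all()
        anchor_rgb = np.clip(skcolor.lab2rgb(
            cfg.stage_palette[2].reshape(1, 1, 3)), 0, 1).reshape(3)
        assert np.array_equal(fruit[0], (anchor_rgb * 255 + 0.5).astype(np.uint8))

    def test_mold_spots_only_at_senescent_stages(self):
        cfg = RenderConfig(image_size=48, noise_sd=0.0,
                           patch_density_by_stage=(0.0,) * 10, mold_spot_rate=8.0)
        t = self._traj()
        mask = fruit_mask(cfg)
        img9, _ = render_fruit_image(t, day=8, side="front", cfg=cfg, rng_seed=1)
        img1, _ = render_fruit_image(t, day=0, side="front", cfg=cfg, rng_seed=1)
        assert len(np.unique(img9[mask], axis=0)) > 1      # mold breaks the flat fill
        assert len(np.unique(img1[mask], axis=0)) == 1

    def test_homogeneous_purple_less_variegated_than_scattered(self):
        # scattered-purple phase (5-stage 3 ~ RI10 6) shows more within-fruit
        # color variance than the homogeneous-purple phase (5-stage 4 ~ RI10 8)
        cfg = RenderConfig(image_size=48, noise_sd=0.0, mold_spot_rate=0.0)
        t = self._traj()
        mask = fruit_mask(cfg)
        img3, _ = render_fruit_image(t, day=5, side="front", cfg=cfg, rng_seed=2)
        img4, _ = render_fruit_image(t, day=7, side="front", cfg=cfg, rng_seed=2)
        var3 = img3[mask].astype(float).var(axis=0).sum()
        var4 = img4[mask].astype(float).var(axis=0).sum()
        assert var4 < var3

    def test_blemish_only_on_assigned_side(self):
        p = FruitParams(1, UNIT_GROUP, 1.0, 1, "front", 1.0)
        t = stage_timeline(p, rng=0, cfg=NOISELESS)
        cfg = self._flat_cfg()
        front, _ = render_fruit_image(t, 0, "front", cfg, 3)
        back, _ = render_fruit_image(t, 0, "back", cfg, 3)
        mask = fruit_mask(cfg)
        assert len(np.unique(front[mask], axis=0)) > 1
        assert len(np.unique(back[mask], axis=0)) == 1

    def test_day_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="day"):
            render_fruit_image(self._traj(), day=99, side="front",
                               cfg=self._flat_cfg(), rng_seed=0)


class TestSimulateCohort:
    def test_default_cohort_has_478_fruits(self):
        traj, records = simulate_cohort(CohortConfig(), 5)
        assert len(traj) == 478
        assert records["sample_id"].nunique() == 478
        assert records.groupby("group")["sample_id"].nunique().to_dict() == {
            "T10": 192, "T20": 143, "Tamb": 143}

    def test_two_sides_per_fruit_per_day(self, small_cohort):
        _, trajectories, records = small_cohort
        per_fruit = records.groupby("sample_id").size()
        for t in trajectories:
            assert per_fruit[t.params.sample_id] == 2 * t.n_days
        assert set(records["side"]) == {"front", "back"}

    def test_ri5_consistent_with_ri10(self, small_cohort):
        _, _, records = small_cohort
        assert (records["ri5"] == (records["ri10"] + 1) // 2).all()

    def test_same_seed_identical_metadata(self):
        cfg = CohortConfig(group_sizes={"T20": 5})
        _, a = simulate_cohort(cfg, 9)
        _, b = simulate_cohort(cfg, 9)
        pd.testing.assert_frame_equal(a, b)

    def test_days_left_zero_on_endpoint_day(self, small_cohort):
        _, _, records = small_cohort
        reached = records[~records["censored"]]
        at_ep = reached[reached.groupby("sample_id")["days_left9"].transform("min")
                        == reached["days_left9"]]
        assert (at_ep["days_left9"] == 0).all()

    def test_rendered_lightness_decreases_through_ripening(self):
        # mean L* of fruit pixels strictly decreases from stage-1 to stage-8
        from skimage import color as skcolor

        cfg = RenderConfig(image_size=48)
        p = FruitParams(1, UNIT_GROUP, 1.0, 1, "none", 0.0)
        t = stage_timeline(p, rng=0, cfg=NOISELESS)
        mask = fruit_mask(cfg)
        Ls = []
        for day in range(8):   # stages 1..8
            img, _ = render_fruit_image(t, day, "front", cfg, rng_seed=day)
            Ls.append(skcolor.rgb2lab(img / 255.0)[mask][:, 0].mean())
        assert np.all(np.diff(Ls) < 0)
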