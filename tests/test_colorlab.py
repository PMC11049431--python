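"""Color pipeline: segmentation, calibration, palettes, aggregation."""

import numpy as np
import pytest
from skimage import color as skcolor

from avoshelf.colorlab import (LabColor, Palette, aggregate_palettes, extract_palette,
                               fit_color_calibration, palette_table, segment_foreground,
                               swatch_image)
from avoshelf.synthetic_orchard import RenderConfig, fruit_mask


def _lab_img(lab_blocks, block=12):
    """Horizontal strip of solid Lab blocks rendered to sRGB float."""
    lab = np.repeat(np.asarray(lab_blocks, float)[None, :, :], block, axis=0)
    lab = np.repeat(lab, block, axis=1)
    return np.clip(skcolor.lab2rgb(lab), 0, 1)


class TestSegmentation:
    def test_all_white_gives_empty_mask(self):
        img = np.ones((32, 32, 3))
        mask = segment_foreground(img)
        assert mask.dtype == bool and mask.shape == (32, 32)
        assert not mask.any()

    def test_rendered_fruit_recovered_with_high_iou(self, small_db, small_cohort):
        _, trajectories, _ = small_cohort
        cfg = RenderConfig(image_size=48)
        truth = fruit_mask(cfg)
        row = small_db.records.iloc[0]
        img = small_db.load_image(row["sample_id"], row["side"], row["day"])
        mask = segment_foreground(img)
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_mask_binary_and_shaped(self, small_db):
        row = small_db.records.iloc[5]
        img = small_db.load_image(row["sample_id"], row["side"], row["day"])
        mask = segment_foreground(img)
        assert mask.dtype == bool and mask.shape == img.shape[:2]


class TestCalibration:
    def test_identity_when_device_matches_reference(self, rng):
        patches = rng.uniform([20, -40, -40], [90, 40, 40], size=(12, 3))
        model = fit_color_calibration(patches, patches)
        assert model.residual_rms < 1e-9
        np.testing.assert_allclose(model.apply(patches), patches, atol=1e-9)

    def test_known_affine_distortion_recovered(self, rng):
        ref = rng.uniform([20, -40, -40], [90, 40, 40], size=(20, 3))
        A = np.array([[0.9, 0.02, 0.0], [-0.01, 1.1, 0.05], [0.0, 0.03, 0.95]])
        b = np.array([2.0, -1.0, 0.5])
        device = ref @ A.T + b          # distort; calibration must invert
        model = fit_color_calibration(device, ref)
        assert model.residual_rms < 1e-6
        np.testing.assert_allclose(model.apply(device), ref, atol=1e-6)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            fit_color_calibration(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_quadratic_model_fits_curvature(self, rng):
        ref = rng.uniform([20, -30, -30], [90, 30, 30], size=(40, 3))
        device = ref + 0.001 * ref ** 2
        m2 = fit_color_calibration(device, ref, degree=2)
        assert m2.residual_rms < 0.05


class TestExtractPalette:
    def test_planted_five_blocks_recovered(self):
        # all five planted colors lie inside the sRGB gamut (lossless round trip)
        blocks = [[80, -30, 40], [60, 40, 30], [45, -30, 0], [30, 20, -30], [15, 0, 0]]
        img = _lab_img(blocks)
        mask = np.ones(img.shape[:2], bool)
        pal = extract_palette(img, mask, k=5, seed=0)
        assert len(pal) == 5
        np.testing.assert_allclose(pal.weights, 0.2, atol=1e-9)
        got = sorted(map(tuple, pal.lab))
        for want, have in zip(sorted(map(tuple, blocks)), got):
            assert np.linalg.norm(np.array(want) - np.array(have)) < 0.5

    def test_uniform_image_single_color(self):
        img = _lab_img([[50, 10, 10]])
        pal = extract_palette(img, np.ones(img.shape[:2], bool), k=5, seed=0)
        assert len(pal) == 1 and pal.weights[0] == 1.0

    def test_deterministic_given_seed(self, small_db):
        row = small_db.records.iloc[3]
        img = small_db.load_image(row["sample_id"], row["side"], row["day"])
        mask = segment_foreground(img)
        a = extract_palette(img, mask, seed=4)
        b = extract_palette(img, mask, seed=4)
        assert a == b

    def test_weights_sum_to_one(self, small_db):
        row = small_db.records.iloc[10]
        img = small_db.load_image(row["sample_id"], row["side"], row["day"])
        mask = segment_foreground(img)
        pal = extract_palette(img, mask, seed=0)
        assert pal.weights.sum() == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        img = np.ones((8, 8, 3))
        with pytest.raises(ValueError, match="empty"):
            extract_palette(img, np.zeros((8, 8), bool))


class TestAggregatePalettes:
    def test_identical_palettes_reproduced(self):
        pal = Palette(tuple(LabColor(L, a, b, w) for (L, a, b), w in
                            zip([[70, -20, 30], [50, 10, 10], [30, 5, -10]],
                                [0.5, 0.3, 0.2])))
        agg = aggregate_palettes([pal] * 10, m=3, seed=0)
        np.testing.assert_allclose(sorted(map(tuple, agg.lab)),
                                   sorted(map(tuple, pal.lab)), atol=1e-6)

    def test_planted_six_colors_recovered(self, rng):
        centers = np.array([[85, -30, 45], [65, 35, 30], [50, -45, -15],
                            [35, 25, -45], [20, 0, 0], [75, 5, -35]], float)
        palettes = []
        for _ in range(40):
            idx = rng.permutation(6)[:5]
            cols = centers[idx] + rng.normal(0, 0.15, size=(5, 3))
            w = rng.dirichlet(np.ones(5))
            order = np.argsort(-w)
            palettes.append(Palette(tuple(
                LabColor(*cols[i], weight=float(w[i])) for i in order)))
        agg = aggregate_palettes(palettes, m=6, seed=1)
        for c in centers:
            assert min(np.linalg.norm(agg.lab - c, axis=1)) < 1.0

    def test_weights_nonincreasing(self, rng):
        palettes = []
        for _ in range(8):
            w = rng.dirichlet(np.ones(4))
            order = np.argsort(-w)
            cols = rng.uniform([20, -40, -40], [90, 40, 40], size=(4, 3))
            palettes.append(Palette(tuple(
                LabColor(*cols[i], weight=float(w[i])) for i in order)))
        agg = aggregate_palettes(palettes, m=5, seed=2)
        assert np.all(np.diff(agg.weights) <= 1e-12)

    def test_m_exceeding_distinct_entries_rejected(self):
        pal = Palette((LabColor(50, 0, 0, 1.0),))
        with pytest.raises(ValueError, match="exceeds"):
            aggregate_palettes([pal], m=6)


class TestCohortDarkening:
    def test_stage1_leads_with_higher_lightness_than_stage8(self, small_db):
        """Aggregate palettes of early vs late renders reflect skin darkening."""
        def agg_for(stage):
            pals = []
            rows = small_db.records[small_db.records["ri10"] == stage].head(6)
            for r in rows.itertuples(index=False):
                img = small_db.load_image(r.sample_id, r.side, r.day)
                mask = segment_foreground(img)
                pals.append(extract_palette(img, mask, seed=0))
            return aggregate_palettes(pals, m=3, seed=0)

        early, late = agg_for(1), agg_for(8)
        assert early.colors[0].L_star > late.colors[0].L_star


class TestPaletteOutputs:
    def test_table_and_swatch_shapes(self):
        pal = Palette((LabColor(70, -20, 30, 0.7), LabColor(30, 5, -10, 0.3)))
        table = palette_table(pal)
        assert list(table["rank"]) == [1, 2]
        assert set(table.columns) == {"rank", "L_star", "a_star", "b_star",
                                      "R", "G", "B", "weight"}
        sw = swatch_image(pal, height=10, block=15)
        assert sw.shape == (10, 30, 3) and sw.dtype == np.uint8
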