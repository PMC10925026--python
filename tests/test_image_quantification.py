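"""Fluorescence preprocessing, segmentation and dye-positive counting."""

import numpy as np
import pytest

from myodti.image_quantification import (
    FiberLabelMap,
    SectionImage,
    SectionQuantification,
    control_intensity_threshold,
    foreground_mask,
    preprocess,
    quantify_sample,
    restrict_to_indented_area,
    score_dye_positive,
    segment_fibers,
    tissue_mask,
)
from myodti.synthetic_data import generate_scene

from conftest import BACKGROUND_RADIUS


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        out = preprocess(np.full((64, 64), 0.7), background_radius=10)
        assert np.all(out == 0.0)

    def test_bright_disk_survives_background_subtraction(self):
        # a feature smaller than the opening disk is retained, the flat
        # background removed; oracle is the rendered ground truth
        img = np.full((96, 96), 0.3)
        rr, cc = np.mgrid[0:96, 0:96]
        disk_mask = (rr - 48) ** 2 + (cc - 48) ** 2 <= 5**2
        img[disk_mask] = 0.9
        out = preprocess(img, background_radius=15)
        assert out[disk_mask].mean() > 0.8
        assert out[~disk_mask].mean() < 0.05

    def test_output_range_contract(self):
        rng = np.random.default_rng(0)
        out = preprocess(rng.random((80, 80)) * 37.0, background_radius=8)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((10, 10)), background_radius=0)


class TestControlThreshold:
    def test_uniform_section(self):
        dye = np.full((32, 32), 0.2)
        mask = np.ones((32, 32), dtype=bool)
        assert control_intensity_threshold([dye], [mask]) == pytest.approx(0.2)

    def test_pooled_mean_of_two_sections(self):
        shape = (32, 32)
        mask = np.ones(shape, dtype=bool)
        thr = control_intensity_threshold(
            [np.full(shape, 0.1), np.full(shape, 0.3)], [mask, mask]
        )
        assert thr == pytest.approx(0.2)

    def test_matches_hand_computed_pooled_mean(self):
        rng = np.random.default_rng(3)
        dyes = [rng.random((20, 20)) for _ in range(3)]
        masks = [rng.random((20, 20)) > 0.4 for _ in range(3)]
        expected = (
            sum(d[m].sum() for d, m in zip(dyes, masks))
            / sum(m.sum() for m in masks)
        )
        assert control_intensity_threshold(dyes, masks) == pytest.approx(expected)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            control_intensity_threshold(
                [np.ones((8, 8))], [np.zeros((8, 8), dtype=bool)]
            )


class TestSegmentation:
    def test_blank_image_yields_empty_map(self):
        lm = segment_fibers(np.zeros((64, 64)))
        assert lm.n_fibers == 0

    def test_two_touching_disks_split_at_neck(self):
        img = np.zeros((80, 120))
        rr, cc = np.mgrid[0:80, 0:120]
        img[(rr - 40) ** 2 + (cc - 45) ** 2 <= 18**2] = 0.9
        img[(rr - 40) ** 2 + (cc - 75) ** 2 <= 18**2] = 0.9
        lm = segment_fibers(img, min_area=50, peak_min_distance=10, smoothing_sigma=2.0)
        assert lm.n_fibers == 2

    @pytest.mark.parametrize("seed", [50, 51, 52])
    def test_well_separated_fiber_count(self, seed):
        # 200 well-separated fibers (widened interstitial gaps) recovered
        # within +-2 % of the planted ground truth
        scene, img = generate_scene(n_fibers=200, pattern="none", extra_gap=3, seed=seed)
        auto = preprocess(img.auto_channel, BACKGROUND_RADIUS)
        lm = segment_fibers(auto, min_area=100, peak_min_distance=9, smoothing_sigma=3.0)
        assert abs(lm.n_fibers - 200) <= 4

    def test_translation_invariance(self):
        scene, img = generate_scene(n_fibers=400, pattern="none", seed=9,
                                    image_shape=(384, 384))
        auto = preprocess(img.auto_channel, BACKGROUND_RADIUS)
        n0 = segment_fibers(auto).n_fibers
        shifted = np.roll(np.roll(img.auto_channel, 7, axis=0), 11, axis=1)
        n1 = segment_fibers(preprocess(shifted, BACKGROUND_RADIUS)).n_fibers
        assert abs(n1 - n0) <= 0.01 * n0 + 2

    def test_intensity_scale_invariance(self):
        scene, img = generate_scene(n_fibers=300, pattern="none", seed=10,
                                    image_shape=(256, 256))
        n0 = segment_fibers(preprocess(img.auto_channel, BACKGROUND_RADIUS)).n_fibers
        n1 = segment_fibers(preprocess(img.auto_channel * 7.3, BACKGROUND_RADIUS)).n_fibers
        assert n1 == n0


class TestIndentedArea:
    @pytest.fixture()
    def label_map(self):
        labels = np.zeros((60, 60), dtype=int)
        centers = [(10, 10), (30, 30), (50, 50)]
        for i, (r, c) in enumerate(centers, start=1):
            labels[r - 3:r + 3, c - 3:c + 3] = i
        return FiberLabelMap.from_labels(labels)

    def test_infinite_radius_is_identity(self, label_map):
        out = restrict_to_indented_area(label_map, (30, 30), np.inf)
        assert out.n_fibers == label_map.n_fibers

    def test_all_outside_yields_empty(self, label_map):
        out = restrict_to_indented_area(label_map, (-100, -100), 5.0)
        assert out.n_fibers == 0

    def test_exact_retention_inside_disk(self, label_map):
        out = restrict_to_indented_area(label_map, (30, 30), 10.0)
        assert out.n_fibers == 1
        np.testing.assert_allclose(out.centroids[0], (29.5, 29.5))


class TestScoring:
    @pytest.fixture()
    def simple_map(self):
        labels = np.zeros((20, 40), dtype=int)
        labels[5:15, 5:15] = 1
        labels[5:15, 25:35] = 2
        dye = np.zeros((20, 40))
        dye[labels == 1] = 0.1
        dye[labels == 2] = 0.8
        return FiberLabelMap.from_labels(labels), dye

    def test_threshold_above_maximum_yields_zero(self, simple_map):
        lm, dye = simple_map
        assert score_dye_positive(lm, dye, 0.9).n_positive == 0

    def test_zero_threshold_marks_all_positive_fibers(self, simple_map):
        lm, dye = simple_map
        q = score_dye_positive(lm, dye, 0.0)
        assert q.n_positive == q.n_fibers == 2

    def test_separating_threshold(self, simple_map):
        lm, dye = simple_map
        q = score_dye_positive(lm, dye, 0.4)
        assert q.n_positive == 1
        assert q.positive_centroids[0][1] == pytest.approx(29.5)

    def test_shape_mismatch_rejected(self, simple_map):
        lm, _ = simple_map
        with pytest.raises(ValueError):
            score_dye_positive(lm, np.zeros((5, 5)), 0.1)

    def test_count_monotone_in_threshold(self):
        scene, img = generate_scene(n_fibers=800, pattern="scattered",
                                    dead_fraction=0.1875, seed=77)
        auto = preprocess(img.auto_channel, BACKGROUND_RADIUS)
        dye = preprocess(img.dye_channel, BACKGROUND_RADIUS)
        lm = segment_fibers(auto)
        counts = [score_dye_positive(lm, dye, thr).n_positive
                  for thr in np.linspace(0.0, 1.0, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_dead_count_recovered(self, dye_threshold):
        scene, img = generate_scene(n_fibers=800, pattern="scattered",
                                    dead_fraction=0.1875, seed=104)
        auto = preprocess(img.auto_channel, BACKGROUND_RADIUS)
        dye = preprocess(img.dye_channel, BACKGROUND_RADIUS)
        q = score_dye_positive(segment_fibers(auto), dye, dye_threshold)
        assert abs(q.n_positive - 150) / 150 <= 0.05


class TestQuantifySample:
    def test_mean_of_counts(self):
        quants = [SectionQuantification(c, 800, np.empty((0, 2)), 0.2)
                  for c in (100, 120)]
        with pytest.warns(UserWarning):
            assert quantify_sample(quants) == pytest.approx(110.0)

    def test_six_equal_counts(self):
        quants = [SectionQuantification(42, 800, np.empty((0, 2)), 0.2)] * 6
        assert quantify_sample(quants) == 42.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantify_sample([])


def test_section_image_validation():
    with pytest.raises(ValueError):
        SectionImage(np.ones((4, 4)), np.ones((5, 5)))
    with pytest.raises(ValueError):
        SectionImage(np.ones((4, 4)), np.full((4, 4), np.nan))
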