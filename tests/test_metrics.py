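"""Image-quality, segmentation and clustering metrics against hand oracles."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from spidesr.metrics import (ClusterAssignment, LabelMask, ch_score, db_score,
                             expression_distance, extraction_accuracy,
                             f1_pixel, iou, match_cells, pearson, psnr,
                             quantify_cells, ssim)
from spidesr.io import ImageGrid


class TestPsnr:
    def test_identical_images_infinite(self):
        x = np.random.default_rng(0).uniform(0, 255, (8, 8))
        assert psnr(x, x) == np.inf

    def test_unit_mse_closed_form(self):
        x = np.zeros((10, 10))
        assert psnr(x, x + 1.0) == pytest.approx(10 * np.log10(255 ** 2))

    def test_halving_mse_adds_3dB(self):
        x = np.zeros((10, 10))
        d = psnr(x, x + 1.0) - psnr(x, x + np.sqrt(2.0))
        assert d == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_channel_average(self):
        x = np.zeros((2, 4, 4))
        y = x.copy()
        y[0] += 1.0   # channel 0: MSE 1; channel 1: identical -> inf
        assert psnr(x, y) == np.inf
        y[1] += 2.0
        expected = (10 * np.log10(255 ** 2) + 10 * np.log10(255 ** 2 / 4)) / 2
        assert psnr(x, y) == pytest.approx(expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 5)))


class TestSsim:
    def test_identical_is_one(self):
        x = np.random.default_rng(1).uniform(0, 255, (8, 8))
        assert ssim(x, x) == pytest.approx(1.0)

    def test_constant_extremes(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 255.0)
        expected = 6.5025 / (255 ** 2 + 6.5025)
        assert ssim(x, y) == pytest.approx(expected, rel=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        x, y = rng.uniform(0, 255, (8, 8)), rng.uniform(0, 255, (8, 8))
        assert ssim(x, y) == pytest.approx(ssim(y, x), rel=1e-12)

    def test_windowed_mode_tracks_global_on_stationary_fields(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(100, 150, (64, 64))
        y = x + rng.normal(0, 10, (64, 64))
        g, w = ssim(x, y), ssim(x, y, windowed=True)
        assert abs(g - w) < 0.15


class TestIouF1:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4), bool); m[1:3, 1:3] = True
        assert iou(m, m) == 1.0
        assert f1_pixel(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        b = np.zeros((4, 4), bool); b[3, 3] = True
        assert iou(a, b) == 0.0
        assert f1_pixel(a, b) == 0.0

    def test_shifted_block(self):
        a = np.zeros((4, 4), bool); a[1:3, 0:2] = True
        b = np.zeros((4, 4), bool); b[1:3, 1:3] = True
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_sentinel(self):
        z = np.zeros((3, 3), bool)
        assert iou(z, z) == 1.0

    def test_f1_iou_identity_on_random_masks(self):
        """F1 = 2 IoU / (1 + IoU) exactly, for any mask pair."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.random((8, 8)) > 0.5
            b = rng.random((8, 8)) > 0.5
            if not (a | b).any():
                continue
            v = iou(a, b)
            assert f1_pixel(a, b) == pytest.approx(2 * v / (1 + v), abs=1e-12)


class TestMatchCells:
    def test_identical_masks_all_tp(self):
        lab = np.zeros((6, 6), int)
        lab[0:2, 0:2] = 1
        lab[3:5, 3:5] = 2
        m = match_cells(LabelMask(lab), LabelMask(lab))
        assert m.tp == 2 and m.fp == 0 and m.fn == 0
        assert all(v == 1.0 for _, _, v in m.tp_pairs)

    def test_empty_prediction(self):
        ref = np.zeros((10, 10), int)
        for i in range(5):
            ref[2 * i, 0] = i + 1
        m = match_cells(LabelMask(np.zeros((10, 10), int)), LabelMask(ref))
        assert (m.tp, m.fp, m.fn) == (0, 0, 5)

    def test_greedy_resolves_double_overlap(self):
        """Two predictions on one reference cell: best IoU wins, other is FP."""
        ref = np.zeros((6, 6), int)
        ref[0:2, 0:5] = 1                     # 10 px
        pred = np.zeros((6, 6), int)
        pred[0, 0:5] = 1                      # 6 px subset -> IoU 0.6
        pred[1, 0] = 1
        pred[1, 2:5] = 2                      # 3 px subset -> IoU 0.3
        m = match_cells(LabelMask(pred), LabelMask(ref))
        assert m.tp_pairs == [(1, 1, pytest.approx(0.6))]
        assert m.fp_labels == [2]
        assert m.fn_labels == []

    def test_threshold_excludes_weak_overlap(self):
        ref = np.zeros((4, 4), int); ref[0:2, 0:2] = 1
        pred = np.zeros((4, 4), int); pred[1, 1] = 1   # IoU 0.25
        m = match_cells(LabelMask(pred), LabelMask(ref), iou_threshold=0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)


class TestExtractionAccuracy:
    def _match(self, tp, fp, fn):
        from spidesr.metrics import MatchResult
        return MatchResult([(i, i, 1.0) for i in range(tp)],
                           list(range(fp)), list(range(fn)))

    def test_printed_form_caps_at_half(self):
        assert extraction_accuracy(self._match(10, 0, 0)) == pytest.approx(0.5)

    def test_f1_style_variant(self):
        assert extraction_accuracy(self._match(10, 0, 0),
                                   variant="f1") == pytest.approx(1.0)

    def test_no_true_positives(self):
        assert extraction_accuracy(self._match(0, 3, 2)) == 0.0

    def test_degenerate_sentinel(self):
        assert np.isnan(extraction_accuracy(self._match(0, 0, 0)))


class TestQuantifyCells:
    def test_mean_of_two_pixels(self):
        mask = LabelMask(np.array([[1, 1], [0, 0]]))
        chan = {"m": ImageGrid(np.array([[10.0, 20.0], [0.0, 0.0]]))}
        table = quantify_cells(chan, mask)
        assert table.loc[0, "m_mean"] == pytest.approx(15.0)

    def test_censoring_caps_outlier_at_one(self):
        rng = np.random.default_rng(5)
        n, side = 200, 40
        mask = np.zeros((side, side), int)
        img = np.zeros((side, side))
        vals = rng.uniform(10, 20, n)
        vals[0] = 250.0   # outlier ~10x above the 99th percentile
        for i in range(n):
            r, c = divmod(i, side)
            mask[r, c] = i + 1
            img[r, c] = vals[i]
        table = quantify_cells({"m": ImageGrid(img)}, LabelMask(mask))
        p99 = np.percentile(vals, 99)
        assert table["m_norm"].max() == pytest.approx(1.0)
        assert table.loc[0, "m_norm"] == pytest.approx(1.0)  # censored to p99
        assert table.loc[0, "m_mean"] == pytest.approx(250.0)
        assert table.loc[1, "m_norm"] == pytest.approx(vals[1] / p99)

    def test_uniform_expressions_normalize_to_one(self):
        mask = LabelMask(np.array([[1, 0, 2], [0, 3, 0]]))
        chan = {"m": ImageGrid(np.full((2, 3), 50.0))}
        table = quantify_cells(chan, mask)
        np.testing.assert_allclose(table["m_norm"], 1.0)

    def test_empty_mask_empty_table(self):
        table = quantify_cells({}, LabelMask(np.zeros((4, 4), int)))
        assert len(table) == 0

    def test_spatial_features(self):
        mask = LabelMask(np.pad(np.ones((2, 2), int), 2))
        table = quantify_cells({}, mask)
        assert table.loc[0, "area"] == 4
        assert table.loc[0, "perimeter"] == 8  # 2x2 block: 8 exposed edges

    def test_normalization_idempotent(self):
        """Censor/normalize is a no-op on an already-normalized value set
        (whenever enough values tie at the cap for the interpolated
        percentile to land exactly on 1)."""
        rng = np.random.default_rng(6)
        vals = np.concatenate([rng.uniform(10, 20, 196), [100.0] * 4])
        p = np.percentile(vals, 99)
        once = np.minimum(vals, p) / p
        p2 = np.percentile(once, 99)
        assert p2 == 1.0
        np.testing.assert_array_equal(np.minimum(once, p2) / p2, once)


class TestExpressionDistance:
    def test_identical_zero(self):
        assert expression_distance([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_three_four_five(self):
        assert expression_distance([0, 0], [3, 4]) == pytest.approx(5.0)

    def test_symmetric(self):
        a, b = [0.1, 0.9, 0.4], [0.5, 0.2, 0.8]
        assert expression_distance(a, b) == expression_distance(b, a)

    def test_channel_mismatch(self):
        with pytest.raises(ValueError):
            expression_distance([1, 2], [1, 2, 3])


class TestClusteringScores:
    def _two_clusters(self):
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        return ClusterAssignment(pts, np.array([0, 0, 1, 1]))

    def test_ch_hand_value(self):
        # tr(B) = 100, tr(W) = 1, CH = 100 * (4-2) / (1 * (2-1)) = 200
        assert ch_score(self._two_clusters()) == pytest.approx(200.0)

    def test_db_hand_value(self):
        # S_i = 0.5 each, M = 10 -> DB = (0.5+0.5)/10 = 0.1
        assert db_score(self._two_clusters()) == pytest.approx(0.1)

    def test_ch_increases_when_points_duplicated(self):
        a = self._two_clusters()
        doubled = ClusterAssignment(np.vstack([a.points, a.points]),
                                    np.concatenate([a.labels, a.labels]))
        assert ch_score(doubled) > ch_score(a)

    def test_ch_degenerate_sentinel(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        a = ClusterAssignment(pts, np.array([0, 0, 1, 1]))
        assert ch_score(a) == np.inf

    def test_db_scale_invariant(self):
        a = self._two_clusters()
        scaled = ClusterAssignment(a.points * 37.5, a.labels)
        assert db_score(scaled) == pytest.approx(db_score(a), rel=1e-12)

    def test_db_coincident_centroids_raise(self):
        pts = np.array([[0.0], [2.0], [0.0], [2.0]])
        a = ClusterAssignment(pts, np.array([0, 0, 1, 1]))
        with pytest.raises(ZeroDivisionError):
            db_score(a)

    def test_matches_sklearn_on_random_data(self):
        """Independent cross-check against sklearn's implementations."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.normal(size=(30, 3))
            labels = rng.integers(0, 3, 30)
            if len(np.unique(labels)) < 2:
                continue
            a = ClusterAssignment(pts, labels)
            assert ch_score(a) == pytest.approx(
                calinski_harabasz_score(pts, labels), rel=1e-9)
            assert db_score(a) == pytest.approx(
                davies_bouldin_score(pts, labels), rel=1e-9)

    def test_planted_structure_beats_random_labels(self):
        """CH rises and DB falls when labels switch from random to planted."""
        rng = np.random.default_rng(8)
        wins_ch = wins_db = 0
        n_draws = 20
        for _ in range(n_draws):
            mu = 5.0  # separation 5 sigma
            pts = np.vstack([rng.normal(0, 1, (20, 2)),
                             rng.normal(mu, 1, (20, 2))])
            planted = np.repeat([0, 1], 20)
            permuted = rng.permutation(planted)
            if len(np.unique(permuted)) < 2:
                continue
            a_p = ClusterAssignment(pts, planted)
            a_r = ClusterAssignment(pts, permuted)
            wins_ch += ch_score(a_p) > ch_score(a_r)
            wins_db += db_score(a_p) < db_score(a_r)
        assert wins_ch == n_draws and wins_db == n_draws


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_sentinel(self):
        assert np.isnan(pearson([1, 1, 1], [1, 2, 3]))
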