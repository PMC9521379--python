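"""Evaluation metrics against hand-computed and brute-force oracles."""
import numpy as np
import pytest
from scipy import ndimage

from saen.metrics import (dice_score, evaluate_pair, hausdorff95, lesion_f1,
                          size_stratified_recall, voxel_recall)


def brute_force_h95(pred, gt):
    """All-pairs boundary distances, 95th percentile, symmetrized."""
    def boundary(m):
        er = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
        return np.argwhere(m & ~er)

    pb, gb = boundary(pred.astype(bool)), boundary(gt.astype(bool))
    d = np.sqrt(((pb[:, None, :] - gb[None, :, :]) ** 2).sum(-1)).astype(float)
    return max(np.percentile(d.min(axis=1), 95), np.percentile(d.min(axis=0), 95))


class TestDice:
    def test_identity_disjoint_and_partial(self):
        a = np.zeros((8, 8), np.uint8)
        a[2:4, 2:4] = 1
        assert dice_score(a, a) == 1.0
        b = np.zeros_like(a)
        b[6:8, 6:8] = 1
        assert dice_score(a, b) == 0.0
        # 4-px pred overlapping 8-px gt in 2 px -> 2*2/(4+8) = 1/3
        pred = np.zeros((8, 8), np.uint8)
        pred[0, 0:4] = 1
        gt = np.zeros_like(pred)
        gt[0:2, 2:6] = 1
        assert np.isclose(dice_score(pred, gt), 1 / 3)

    def test_both_empty_is_perfect_agreement(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice_score(z, z) == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((10, 10)) < 0.3
            b = rng.random((10, 10)) < 0.3
            d = dice_score(a, b)
            assert d == dice_score(b, a)
            assert 0.0 <= d <= 1.0

    def test_dilating_prediction_toward_gt_never_decreases_dice(self):
        gt = np.zeros((16, 16), np.uint8)
        gt[4:12, 4:12] = 1
        pred = np.zeros_like(gt)
        pred[7:9, 7:9] = 1
        last = dice_score(pred, gt)
        for _ in range(3):
            pred = ndimage.binary_dilation(pred) & gt.astype(bool)
            d = dice_score(pred.astype(np.uint8), gt)
            assert d >= last
            last = d

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            dice_score(np.zeros((3, 3)), np.zeros((4, 4)))


class TestHausdorff95:
    def test_identity_is_zero(self):
        m = np.zeros((10, 10), np.uint8)
        m[3:7, 3:7] = 1
        v, ok = hausdorff95(m, m)
        assert v == 0.0 and ok

    def test_two_single_pixels(self):
        a = np.zeros((12, 12), np.uint8)
        b = np.zeros_like(a)
        a[4, 2] = 1
        b[4, 7] = 1
        v, ok = hausdorff95(a, b)
        assert ok and v == 5.0

    def test_shifted_square_matches_brute_force(self):
        a = np.zeros((20, 20), np.uint8)
        a[5:15, 5:15] = 1
        b = np.zeros_like(a)
        b[5:15, 8:18] = 1
        v, ok = hausdorff95(a, b)
        assert ok
        assert v == pytest.approx(brute_force_h95(a, b), abs=1e-12)

    def test_percentile_bounded_by_exact_hausdorff(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = ndimage.binary_dilation(rng.random((16, 16)) < 0.05, iterations=2)
            b = ndimage.binary_dilation(rng.random((16, 16)) < 0.05, iterations=2)
            if not a.any() or not b.any():
                continue
            v, _ = hausdorff95(a, b)
            exact = brute_force_h95(a, b) if False else None
            # exact (100th percentile) all-pairs Hausdorff
            def bpts(m):
                er = ndimage.binary_erosion(
                    m, structure=ndimage.generate_binary_structure(2, 1), border_value=0)
                return np.argwhere(m & ~er)
            pa, pb = bpts(a), bpts(b)
            d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
            hd = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert v <= hd + 1e-12

    def test_spacing_scales_distances(self):
        a = np.zeros((6, 6), np.uint8)
        b = np.zeros_like(a)
        a[1, 1] = 1
        b[1, 4] = 1
        v, _ = hausdorff95(a, b, spacing=(1.0, 2.0))
        assert v == 6.0

    def test_empty_mask_gives_flagged_sentinel(self):
        m = np.zeros((10, 10), np.uint8)
        g = np.zeros_like(m)
        g[2, 2] = 1
        v, ok = hausdorff95(m, g)
        assert not ok
        assert v == pytest.approx(np.sqrt(200))


class TestVoxelRecall:
    def test_superset_disjoint_and_counts(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[1:3, 1:3] = 1
        assert voxel_recall(np.ones_like(gt), gt) == 1.0
        assert voxel_recall(np.zeros_like(gt), gt) == 0.0
        pred = np.zeros_like(gt)
        pred[1, 1] = 1
        pred[0, 0] = 1  # false positive does not affect recall
        assert voxel_recall(pred, gt) == 0.25

    def test_empty_gt_is_undefined(self):
        assert np.isnan(voxel_recall(np.ones((3, 3)), np.zeros((3, 3))))


class TestLesionWise:
    def _three_blobs(self):
        gt = np.zeros((12, 12), np.uint8)
        gt[1:3, 1:3] = 1
        gt[1:3, 8:10] = 1
        gt[8:11, 4:8] = 1
        return gt

    def test_perfect_prediction(self):
        gt = self._three_blobs()
        recall, f1, det, n = lesion_f1(gt, gt)
        assert (recall, f1, det, n) == (1.0, 1.0, 3, 3)

    def test_empty_prediction(self):
        gt = self._three_blobs()
        recall, f1, det, n = lesion_f1(np.zeros_like(gt), gt)
        assert recall == 0.0 and f1 == 0.0 and det == 0 and n == 3

    def test_one_hit_one_false_positive(self):
        gt = np.zeros((12, 12), np.uint8)
        gt[1:3, 1:3] = 1
        gt[8:10, 8:10] = 1
        pred = np.zeros_like(gt)
        pred[1:3, 1:3] = 1      # hits lesion 1
        pred[5, 5] = 1          # spurious blob
        recall, f1, det, n = lesion_f1(pred, gt)
        assert recall == 0.5
        assert f1 == pytest.approx(0.5)  # 2*1/(2*1+1+1)

    def test_single_voxel_lesions_match_voxel_recall(self):
        rng = np.random.default_rng(5)
        gt = np.zeros((9, 9), np.uint8)
        pts = [(1, 1), (1, 7), (4, 4), (7, 2), (7, 7)]
        for y, x in pts:
            gt[y, x] = 1
        pred = (rng.random((9, 9)) < 0.4).astype(np.uint8)
        recall, _, _, _ = lesion_f1(pred, gt)
        assert recall == voxel_recall(pred, gt)

    def test_eight_connectivity_merges_diagonal(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[0, 0] = 1
        gt[1, 1] = 1  # diagonal neighbour: one lesion under 8-connectivity
        _, _, _, n = lesion_f1(gt, gt)
        assert n == 1


class TestSizeStratified:
    def test_partition_at_median(self):
        gt = np.zeros((24, 24), np.uint8)
        gt[0, 0:2] = 1                 # size 2
        gt[4:6, 4:9] = 1               # size 10
        gt[12:17, 10:20] = 1           # size 50
        pred = np.zeros_like(gt)
        pred[12:17, 10:20] = 1         # only the large lesion detected
        r_large, r_small, median = size_stratified_recall(pred, gt)
        assert median == 10
        assert r_large == 1.0
        assert r_small == 0.0

    def test_all_detected(self):
        gt = np.zeros((10, 10), np.uint8)
        gt[0:2, 0:2] = 1
        gt[6:9, 6:9] = 1
        r_large, r_small, _ = size_stratified_recall(gt, gt)
        assert r_small == 1.0 and r_large == 1.0

    def test_single_lesion_is_small_stratum(self):
        gt = np.zeros((8, 8), np.uint8)
        gt[2:4, 2:4] = 1
        r_large, r_small, median = size_stratified_recall(gt, gt)
        assert median == 4
        assert r_small == 1.0
        assert np.isnan(r_large)

    def test_empty_gt_raises(self):
        with pytest.raises(ValueError):
            size_stratified_recall(np.ones((4, 4)), np.zeros((4, 4)))


def test_evaluate_pair_bundles_everything():
    gt = np.zeros((16, 16), np.uint8)
    gt[2:6, 2:6] = 1
    gt[10:12, 10:12] = 1
    r = evaluate_pair(gt, gt)
    assert r.dice == 1.0 and r.h95 == 0.0 and r.recall == 1.0
    assert r.lesion_f1 == 1.0 and r.n_lesions_gt == 2 and r.h95_defined
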