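"""Metric implementations against brute-force oracles and closed forms."""

import numpy as np
import pytest

from glomil.evaluation import (EvalRecord, auc, bootstrap_ci, count_macs, dice,
                               dice_sweep, downsample_mask, grouped_auc,
                               max_project, operating_point, patch_coverage, pxap)


def _auc_pairs_oracle(scores, labels):
    """All-pairs Mann-Whitney with ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _ap_threshold_oracle(scores, truth):
    """Average precision by enumerating every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    ap, prev_recall = 0.0, 0.0
    n_pos = truth.sum()
    for th in sorted(set(scores), reverse=True):
        pred = scores >= th
        tp = (pred & truth).sum()
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestAuc:
    def test_perfect_and_inverted(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_hand_case(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
            assert auc(scores, labels) == pytest.approx(
                _auc_pairs_oracle(scores, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestGroupedAuc:
    def _records(self, scores, labels, groups):
        return [EvalRecord(str(i), g, (0.0, s), (0, y))
                for i, (s, y, g) in enumerate(zip(scores, labels, groups))]

    def test_singleton_groups_equal_imagewise(self, rng):
        scores = rng.random(10)
        labels = [0, 1] * 5
        recs = self._records(scores, labels, range(10))
        assert grouped_auc(recs) == pytest.approx(auc(scores, labels))

    def test_duplicating_records_is_idempotent(self, rng):
        scores = rng.random(6)
        labels = [0, 0, 1, 1, 0, 1]
        recs = self._records(scores, labels, range(6))
        doubled = recs + recs
        assert grouped_auc(doubled) == pytest.approx(grouped_auc(recs))

    def test_two_view_groups_average(self):
        recs = self._records([0.2, 0.4, 0.9, 0.5], [0, 0, 1, 1], [0, 0, 1, 1])
        # group means: 0.3 (neg), 0.7 (pos)
        assert grouped_auc(recs) == 1.0

    def test_inconsistent_group_labels_raise(self):
        recs = self._records([0.2, 0.4], [0, 1], [0, 0])
        with pytest.raises(ValueError, match="inconsistent"):
            grouped_auc(recs)


class TestMaxProject:
    def test_depth_one_identity(self, rng):
        plane = rng.random((4, 5, 1))
        assert np.array_equal(max_project(plane), plane[:, :, 0])

    def test_one_hot_voxel(self):
        stack = np.zeros((4, 4, 3))
        stack[2, 1, 2] = 1.0
        proj = max_project(stack)
        assert proj[2, 1] == 1.0 and proj.sum() == 1.0

    def test_matches_loop_oracle(self, rng):
        stack = rng.random((5, 6, 4))
        proj = max_project(stack)
        for i in range(5):
            for j in range(6):
                assert proj[i, j] == max(stack[i, j, d] for d in range(4))


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(~a, a) == 0.0

    def test_closed_form(self):
        p = np.zeros(10, bool)
        t = np.zeros(10, bool)
        p[:4] = True          # |P| = 4
        t[1:7] = True         # |T| = 6, overlap = 3
        assert dice(p, t) == pytest.approx(0.6)

    def test_symmetry(self, rng):
        p = rng.random((6, 6)) > 0.5
        t = rng.random((6, 6)) > 0.3
        if not t.any() or not p.any():
            pytest.skip("degenerate draw")
        assert dice(p, t) == dice(t, p)

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            dice(np.ones(4, bool), np.zeros(4, bool))


class TestPxap:
    def test_perfect_ranking(self):
        assert pxap(np.array([0.9, 0.8, 0.2, 0.1]),
                    np.array([1, 1, 0, 0])) == 1.0

    def test_constant_saliency_gives_prevalence(self):
        truth = np.array([1, 0, 0, 1, 0])
        assert pxap(np.full(5, 0.5), truth) == pytest.approx(0.4)

    def test_six_pixel_hand_case(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        truth = np.array([1, 0, 1, 0, 0, 1])
        assert pxap(scores, truth) == pytest.approx(
            _ap_threshold_oracle(scores, truth), abs=1e-12)

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 101))
            truth = rng.integers(0, 2, size=n)
            if truth.sum() == 0:
                continue
            scores = rng.choice(np.round(rng.random(8), 3), size=n)
            assert pxap(scores, truth) == pytest.approx(
                _ap_threshold_oracle(scores, truth), abs=1e-10)


class TestDiceSweep:
    def test_best_threshold_recovers_clean_mask(self):
        truth = np.zeros((8, 8), bool)
        truth[2:5, 3:6] = True
        saliency = np.where(truth, 0.9, 0.05)
        out = dice_sweep(saliency, truth)
        assert out["best_dice"] == 1.0
        assert len(out["sweep"]) == 19

    def test_block_max_downsampling_preserves_small_objects(self):
        mask = np.zeros((16, 16, 2), np.uint8)
        mask[5, 5, 1] = 1  # single voxel
        down = downsample_mask(mask, 4)
        assert down.shape == (4, 4, 2)
        assert down[1, 1, 1] == 1 and down.sum() == 1


class TestCountMacs:
    def test_one_by_one_conv_closed_form(self):
        spec = [{"type": "conv2d", "c_out": 2, "kernel": 1}]
        assert count_macs(spec, (64, 100, 80)) == 64 * 2 * 100 * 80

    def test_linear_closed_form(self):
        assert count_macs([{"type": "linear", "c_in": 512, "c_out": 2}],
                          (512,)) == 1024

    def test_additivity(self):
        a = [{"type": "conv2d", "c_out": 8, "kernel": 3, "stride": 2,
              "padding": 1}]
        b = [{"type": "conv2d", "c_out": 16, "kernel": 3, "padding": 1}]
        total = count_macs(a + b, (1, 32, 32))
        first = count_macs(a, (1, 32, 32))
        second = count_macs(b, (8, 16, 16))
        assert total == first + second

    def test_global_cost_linear_in_depth_local_constant(self):
        """Per-slice global MACs scale exactly linearly with D; the
        K-patch local cost does not depend on D at all."""
        from glomil.experiments import desk_config
        from glomil.profile import model_mac_table

        cfg = desk_config()
        tables = {d: model_mac_table(cfg, (64, 64, d)) for d in (10, 20, 40)}
        g10 = tables[10][f"global x D=10 slices"]
        assert tables[20]["global x D=20 slices"] == 2 * g10
        assert tables[40]["global x D=40 slices"] == 4 * g10
        locals_ = {tables[d][f"local x K={cfg.K} patches"] for d in (10, 20, 40)}
        assert len(locals_) == 1

    def test_bad_spec_raises(self):
        with pytest.raises(ValueError):
            count_macs([{"type": "conv3d", "c_out": 4, "kernel": 3}], (1, 8, 8))
        with pytest.raises(ValueError):
            count_macs([{"type": "pool"}], (1, 8, 8))


class TestPatchCoverage:
    def test_worked_examples(self):
        """K = 8 patches of 256x256 = 524,288 pixels: 18.50% of a
        2116x1339 image, 0.26% of the same image with 70 slices."""
        assert 8 * 256 * 256 == 524_288
        _, pct2d = patch_coverage((2116, 1339), 8)
        _, pct3d = patch_coverage((2116, 1339, 70), 8)
        assert pct2d == 18.50
        assert pct3d == 0.26

    def test_zero_patches(self):
        assert patch_coverage((100, 100), 0) == (0.0, 0.0)


class TestUtilities:
    def test_bootstrap_ci_brackets_point(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.5, 1, 40)])
        labels = np.array([0] * 40 + [1] * 40)
        point, lo, hi = bootstrap_ci(auc, scores, labels, n_boot=200)
        assert lo <= point <= hi
        assert 0.7 < point < 1.0

    def test_operating_point_sensitivity_target(self, rng):
        scores = rng.random(50)
        labels = (scores + rng.normal(0, 0.2, 50)) > 0.5
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        op = operating_point(scores, labels, sensitivity=0.9)
        assert op["sensitivity"] >= 0.9
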