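"""Saliency head and slice-count-independent top-t% pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomil.global_module import (FeatureStack, aggregate_top_t, compute_saliency,
                                  extract_slice_features, global_predict,
                                  init_segmentation_layer, pooled_count, relu_tanh)
from glomil.nn import SliceEncoder


class TestReluTanh:
    def test_closed_form_values(self):
        assert relu_tanh(0.0) == 0.0
        assert relu_tanh(-3.2) == 0.0
        assert relu_tanh(1.0) == pytest.approx((np.e**2 - 1) / (np.e**2 + 1),
                                               abs=1e-12)

    @given(st.floats(-50, 50))
    @settings(derandomize=True)
    def test_range_and_clamp(self, v):
        out = relu_tanh(v)
        assert 0.0 <= out <= 1.0
        if v <= 0:
            assert out == 0.0


class TestSegmentationLayer:
    def test_constant_init(self):
        layer = init_segmentation_layer(16, 0.01)
        assert layer.weights.shape == (16, 2)
        assert np.all(layer.weights == 0.01)
        assert np.all(layer.bias == 0.0)

    def test_rejects_nonpositive_omega(self):
        with pytest.raises(ValueError):
            init_segmentation_layer(16, 0.0)

    def test_init_saliency_invariant_to_channel_permutation(self, rng):
        feats = FeatureStack(rng.normal(size=(3, 4, 4, 16)), 16)
        layer = init_segmentation_layer(16, 0.01)
        sal = compute_saliency(feats, layer)
        perm = FeatureStack(feats.values[..., rng.permutation(16)], 16)
        assert np.allclose(compute_saliency(perm, layer), sal)

    def test_omega_search_range(self, rng):
        exponents = rng.uniform(-3, -2, size=100)
        omegas = 10.0 ** exponents
        assert np.all((omegas >= 1e-3) & (omegas <= 1e-2))

    def test_init_saliency_monotone_in_channel_sum(self, rng):
        """At constant init, saliency is a nondecreasing function of the
        per-location channel sum of the backbone activations."""
        feats = FeatureStack(rng.normal(size=(2, 5, 5, 16)), 16)
        layer = init_segmentation_layer(16, 0.005)
        sal = compute_saliency(feats, layer)  # (h, w, D, 2)
        sums = feats.values.sum(axis=-1)      # (D, h, w)
        flat_sum = np.moveaxis(sums, 0, -1).ravel()
        order = np.argsort(flat_sum)
        for c in range(2):
            sal_sorted = sal[..., c].ravel()[order]
            assert np.all(np.diff(sal_sorted) >= -1e-12)


class TestComputeSaliency:
    def test_all_zero_features(self):
        feats = FeatureStack(np.zeros((2, 3, 3, 8)), 16)
        layer = init_segmentation_layer(8, 0.01)
        assert np.all(compute_saliency(feats, layer) == 0.0)

    def test_single_entry_hand_case(self):
        values = np.zeros((4, 3, 3, 8))
        values[2, 1, 1, 0] = 5.0
        feats = FeatureStack(values, 16)
        layer = init_segmentation_layer(8, 0.01)
        sal = compute_saliency(feats, layer)
        assert sal.shape == (3, 3, 4, 2)
        assert sal[1, 1, 2, 0] == pytest.approx(np.tanh(0.05), abs=1e-12)
        assert sal[1, 1, 2, 1] == pytest.approx(np.tanh(0.05), abs=1e-12)
        sal[1, 1, 2, :] = 0
        assert np.all(sal == 0.0)

    def test_negative_features_clamp_to_zero(self, rng):
        feats = FeatureStack(-np.abs(rng.normal(size=(2, 4, 4, 8))) - 0.1, 16)
        layer = init_segmentation_layer(8, 0.02)
        assert np.all(compute_saliency(feats, layer) == 0.0)

    def test_shape_mismatch_raises(self, rng):
        feats = FeatureStack(rng.normal(size=(2, 4, 4, 8)), 16)
        layer = init_segmentation_layer(16, 0.01)
        with pytest.raises(ValueError, match="channel"):
            compute_saliency(feats, layer)


class TestTopTPooling:
    def test_constant_plane_returns_value(self):
        plane = np.full((4, 4, 3), 0.7)
        for t in (5.0, 100.0, 250.0):
            assert aggregate_top_t(plane, t) == pytest.approx(0.7)

    def test_pooled_fraction_worked_example(self):
        """t = 200% of one 16x16 slice pools 512 cells: 4% of a 50-slice
        map, 2.5% of an 80-slice map."""
        n50 = pooled_count(16, 16, 50, 200.0)
        n80 = pooled_count(16, 16, 80, 200.0)
        assert n50 == n80 == 512
        assert n50 / (16 * 16 * 50) == pytest.approx(0.04)
        assert n80 / (16 * 16 * 80) == pytest.approx(0.025)

    def test_count_independent_of_depth(self):
        for t in (10.97, 100.0, 200.0, 274.25):
            counts = {pooled_count(12, 10, d, t) for d in (1, 8, 50, 80, 96)}
            if t <= 100:  # below one slice's worth the cap never binds
                assert len(counts) == 1

    def test_cap_binds_only_for_tiny_planes(self):
        assert pooled_count(4, 4, 1, 274.25) == 16  # capped at h*w*D
        assert pooled_count(4, 4, 2, 274.25) == 32
        assert pooled_count(4, 4, 3, 274.25) == 44  # round(2.7425 * 16)

    def test_matches_full_sort_oracle(self, rng):
        for _ in range(500):
            h, w, d = rng.integers(1, 9), rng.integers(1, 9), rng.integers(1, 7)
            plane = rng.random((h, w, d))
            t = float(rng.uniform(5, 274.25))
            n = pooled_count(h, w, d, t)
            oracle = np.sort(plane.ravel())[plane.size - n:].mean()
            assert aggregate_top_t(plane, t) == oracle

    def test_monotone_in_any_entry(self, rng):
        plane = rng.random((5, 5, 4))
        base = aggregate_top_t(plane, 50.0)
        for _ in range(20):
            idx = tuple(rng.integers(0, s) for s in plane.shape)
            bumped = plane.copy()
            bumped[idx] += rng.uniform(0, 2)
            assert aggregate_top_t(bumped, 50.0) >= base - 1e-15

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            aggregate_top_t(np.empty((0, 4, 4)), 10.0)
        with pytest.raises(ValueError):
            aggregate_top_t(np.ones((4, 4, 2)), 0.0)


class TestGlobalPredict:
    def test_extremes(self):
        assert global_predict(np.zeros((4, 4, 3, 2)), 100.0) == (0.0, 0.0)
        assert global_predict(np.ones((4, 4, 3, 2)), 100.0) == (1.0, 1.0)

    def test_appending_zero_slices_is_invariant(self, rng):
        sal = rng.random((6, 6, 5, 2))
        padded = np.concatenate([sal, np.zeros((6, 6, 4, 2))], axis=2)
        for t in (10.0, 100.0):
            assert global_predict(padded, t) == global_predict(sal, t)


class TestSliceFeatures:
    @pytest.fixture
    def backbone(self, rng):
        return SliceEncoder(width=8, downsample=8, rng=rng)

    def test_per_slice_independence(self, backbone, rng):
        vol = rng.random((32, 32, 4))
        vol[:, :, 3] = vol[:, :, 1]  # duplicate a slice
        feats = extract_slice_features(vol, backbone)
        assert np.allclose(feats.values[3], feats.values[1], atol=1e-10)

    def test_slice_permutation_equivariance(self, backbone, rng):
        vol = rng.random((32, 32, 5))
        perm = np.array([4, 2, 0, 1, 3])
        a = extract_slice_features(vol, backbone).values
        b = extract_slice_features(vol[:, :, perm], backbone).values
        assert np.allclose(b, a[perm], atol=1e-10)

    def test_no_batch_statistics(self, backbone, rng):
        """Features of a slice are identical whether it is encoded alone
        or with other slices (group norm carries no batch coupling)."""
        vol = rng.random((32, 32, 3))
        full = extract_slice_features(vol, backbone).values
        solo = extract_slice_features(vol[:, :, 1:2], backbone).values
        assert np.allclose(full[1], solo[0], atol=1e-5)

    def test_rejects_bad_volumes(self, backbone):
        with pytest.raises(ValueError):
            extract_slice_features(np.empty((32, 32, 0)), backbone)
        bad = np.ones((32, 32, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            extract_slice_features(bad, backbone)

    def test_feature_stack_channel_constraint(self, rng):
        with pytest.raises(ValueError, match="divisible by 8"):
            FeatureStack(rng.normal(size=(2, 4, 4, 12)), 8)


def test_export_saliency_round_trips_per_class(tmp_path, rng):
    from glomil.global_module import export_saliency
    from glomil.io import read_volume

    sal = rng.random((8, 8, 5, 2))
    paths = export_saliency(sal, tmp_path / "case7")
    assert [p.name for p in paths] == ["case7_benign.nii.gz",
                                       "case7_malignant.nii.gz"]
    for c, p in enumerate(paths):
        back = read_volume(p).values
        assert np.allclose(back, sal[..., c], atol=1e-7)
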