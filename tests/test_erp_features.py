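"""Discriminability map, selection and sparse feature-map contracts.

The point-biserial map is cross-checked against a direct Pearson
correlation between single-trial voltage and the 0/1 class label, and the
selection against an exhaustive sorting oracle on small instances.
"""

import numpy as np
import pytest

import neuroauth as na
from tests.conftest import toy_epochset


def _pearson_oracle(x: np.ndarray, labels01: np.ndarray) -> float:
    """Pearson correlation of per-trial voltage with the class indicator."""
    return float(np.corrcoef(x, labels01)[0, 1])


class TestPointwiseBiserial:
    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(6, 2, 5))
        labels = ["self", "self", "self", "nonself", "nonself", "nonself"]
        y = np.array([1, 1, 1, 0, 0, 0])
        dmap = na.pointwise_biserial(toy_epochset(data, labels))
        for ch in range(2):
            for n in range(5):
                expect = _pearson_oracle(data[:, ch, n], y)
                assert dmap.P[ch, n] == pytest.approx(expect, abs=1e-12)

    def test_equal_class_means_zero(self):
        # per-trial offsets that cancel within each class: zero numerator
        data = np.ones((6, 2, 4))
        offsets = np.array([1., -1., 0., 2., -2., 0.])
        data += offsets[:, None, None]
        labels = ["self"] * 3 + ["nonself"] * 3
        dmap = na.pointwise_biserial(toy_epochset(data, labels))
        np.testing.assert_allclose(dmap.P, 0.0, atol=1e-15)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(8, 3, 6))
        labels = ["self"] * 4 + ["nonself"] * 4
        p1 = na.pointwise_biserial(toy_epochset(data, labels)).P
        p2 = na.pointwise_biserial(toy_epochset(2.0 * data, labels)).P
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_requires_two_trials_per_class(self):
        data = np.random.default_rng(0).normal(size=(3, 2, 4))
        with pytest.raises(ValueError, match="two trials"):
            na.pointwise_biserial(
                toy_epochset(data, ["self", "nonself", "nonself"]))

    def test_standard_dimensions(self, epochs):
        dmap = na.pointwise_biserial(epochs)
        assert dmap.P.shape == (16, 600)
        assert np.all(np.isfinite(dmap.P))

    def test_peak_discriminability_near_template_latency(self, epochs,
                                                         profile):
        dmap = na.pointwise_biserial(epochs)
        peak_ms = np.argmax(np.abs(dmap.P).max(axis=0)) / 600.0 * 1000.0
        half_support = 1.5 * profile.erp_width
        assert abs(peak_ms - profile.erp_latency) <= half_support


class TestSelection:
    def test_standard_mask_shape(self, epochs):
        mask = na.select_channels_times(na.pointwise_biserial(epochs))
        assert mask.channels.size == 5
        assert mask.time_indices.shape == (5, 200)
        for row in mask.time_indices:
            assert np.all(np.diff(row) > 0)  # ascending, unique

    def test_dominant_channel_ranks_first(self):
        P = np.abs(np.random.default_rng(3).normal(size=(4, 10))) * 0.1
        P[2] += 5.0
        dmap = na.DiscriminabilityMap(P=P, mean_self=P, mean_nonself=P,
                                      pooled_sd=np.ones_like(P))
        mask = na.select_channels_times(dmap, top_points=4, top_channels=1)
        assert mask.channels.tolist() == [2]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        P = rng.normal(size=(3, 10))
        dmap = na.DiscriminabilityMap(P=P, mean_self=P, mean_nonself=P,
                                      pooled_sd=np.ones_like(P))
        mask = na.select_channels_times(dmap, top_points=4, top_channels=2)
        # oracle: exhaustive sort by (-|P|, index) per channel
        scores = []
        expected_idx = []
        for ch in range(3):
            order = sorted(range(10), key=lambda j: (-abs(P[ch, j]), j))
            keep = sorted(order[:4])
            expected_idx.append(keep)
            scores.append(np.mean(P[ch, keep] ** 2))
        expected_ch = sorted(sorted(range(3),
                                    key=lambda c: (-scores[c], c))[:2])
        assert mask.channels.tolist() == expected_ch
        for row, ch in zip(mask.time_indices, mask.channels):
            assert row.tolist() == expected_idx[ch]

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(4, 8))
        perm = np.array([2, 0, 3, 1])
        d1 = na.DiscriminabilityMap(P=P, mean_self=P, mean_nonself=P,
                                    pooled_sd=np.ones_like(P))
        d2 = na.DiscriminabilityMap(P=P[perm], mean_self=P[perm],
                                    mean_nonself=P[perm],
                                    pooled_sd=np.ones_like(P))
        m1 = na.select_channels_times(d1, top_points=3, top_channels=2)
        m2 = na.select_channels_times(d2, top_points=3, top_channels=2)
        # the same physical channels are selected with the same time indices
        sel1 = {tuple(row) for row in m1.time_indices}
        sel2 = {tuple(row) for row in m2.time_indices}
        assert sel1 == sel2
        assert sorted(perm[m2.channels]) == sorted(m1.channels)


class TestAverageAdjacent:
    def test_two_hundred_to_one_hundred(self):
        data = np.random.default_rng(0).normal(size=(200, 2, 10))
        out = na.average_adjacent_trials(
            toy_epochset(data, ["self"] * 200))
        assert out.n_trials == 100
        np.testing.assert_allclose(out.data[0], data[:2].mean(axis=0))

    def test_identical_trials_unchanged(self):
        one = np.random.default_rng(1).normal(size=(1, 2, 5))
        data = np.repeat(one, 2, axis=0)
        out = na.average_adjacent_trials(toy_epochset(data, ["self"] * 2))
        np.testing.assert_allclose(out.data[0], one[0])

    def test_opposite_trials_cancel(self):
        x = np.random.default_rng(2).normal(size=(1, 2, 5))
        data = np.concatenate([x, -x])
        out = na.average_adjacent_trials(toy_epochset(data, ["self"] * 2))
        np.testing.assert_allclose(out.data, 0.0)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            na.average_adjacent_trials(
                toy_epochset(np.zeros((1, 2, 5)), ["self"]))


class TestFeatureMap:
    def _const_mask(self):
        idx = np.tile(np.arange(200), (5, 1))
        return na.SelectionMask(channels=np.arange(5),
                                time_indices=idx,
                                channel_scores=np.ones(5))

    def test_constant_epoch(self):
        epoch = np.full((16, 720), 3.0)
        fmap = na.build_feature_map(epoch, self._const_mask())
        np.testing.assert_allclose(fmap.compact, 3.0)
        assert fmap.expanded.sum() == pytest.approx(300.0)

    def test_first_window_mean(self):
        epoch = np.zeros((16, 720))
        epoch[0, 120:320] = np.arange(1, 201)  # post-stimulus samples
        fmap = na.build_feature_map(epoch, self._const_mask())
        assert fmap.compact[0, 0] == pytest.approx(5.5)  # mean of 1..10

    def test_sparse_expansion_layout(self):
        compact = np.random.default_rng(0).normal(size=(5, 20))
        exp = na.expand_sparse(compact)
        assert exp.shape == (20, 20)
        np.testing.assert_array_equal(exp[[0, 4, 8, 12, 16]], compact)
        zero_rows = np.delete(np.arange(20), [0, 4, 8, 12, 16])
        assert np.all(exp[zero_rows] == 0)
        assert (exp == 0).sum() >= 300
        assert exp.sum() == pytest.approx(compact.sum())

    def test_linearity_of_window_sum(self):
        rng = np.random.default_rng(9)
        epoch = rng.normal(size=(16, 720))
        mask = self._const_mask()
        fmap = na.build_feature_map(epoch, mask)
        for r, ch in enumerate(mask.channels):
            selected = epoch[ch, 120:][mask.time_indices[r]]
            assert fmap.compact[r].sum() * 10 == pytest.approx(
                selected.sum())

    def test_mask_window_mismatch(self):
        mask = na.SelectionMask(channels=np.arange(5),
                                time_indices=np.tile(np.arange(100), (5, 1)),
                                channel_scores=np.ones(5))
        with pytest.raises(ValueError):
            na.build_feature_map(np.zeros((16, 720)), mask)
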