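"""RkCNN ensemble tests: sampling, selection, weighting, aggregation."""

import logging

import numpy as np
import pytest

from rkcnn.dataset import Dataset
from rkcnn.ensemble import (
    RkCNN,
    RkCNNConfig,
    compute_weights,
    rkcnn_fit,
    rkcnn_predict,
    rkcnn_predict_proba,
    sample_subsets,
    select_top_r,
)
from rkcnn.kcnn import kcnn_predict_batch, kcnn_predict_proba_batch
from rkcnn.separation import FeatureSubset, SubsetScore

from conftest import random_dataset


def _score(s, draw_idx=0):
    subset = FeatureSubset([draw_idx % 2], 2)
    return SubsetScore(subset=subset, bv=s if np.isfinite(s) else 1.0,
                       wv=0.0 if np.isinf(s) else 1.0, s=s)


class TestSampleSubsets:
    def test_m_equals_q_forces_full_set(self):
        for sub in sample_subsets(5, 5, 3, seed=1):
            np.testing.assert_array_equal(sub.indices, np.arange(5))

    def test_contract_sizes_and_ranges(self):
        subs = sample_subsets(10, 3, 4, seed=2)
        assert len(subs) == 4
        for sub in subs:
            assert sub.m == 3
            assert np.unique(sub.indices).size == 3
            assert sub.indices.min() >= 0 and sub.indices.max() < 10

    def test_seed_determinism(self):
        a = sample_subsets(20, 4, 6, seed=7)
        b = sample_subsets(20, 4, 6, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.indices, y.indices)

    def test_growing_h_preserves_earlier_draws(self):
        short = sample_subsets(30, 5, 10, seed=3)
        long = sample_subsets(30, 5, 25, seed=3)
        for x, y in zip(short, long[:10]):
            np.testing.assert_array_equal(x.indices, y.indices)

    def test_m_larger_than_q_rejected(self):
        with pytest.raises(ValueError):
            sample_subsets(3, 4, 1, seed=0)


class TestSelectionAndWeights:
    def test_descending_selection(self):
        top = select_top_r([_score(0.1), _score(5.0), _score(3.0)], 2)
        assert [t.s for t in top] == [5.0, 3.0]

    def test_stable_tie_break_by_draw_order(self):
        scores = [
            SubsetScore(FeatureSubset([i], 5), bv=2.0, wv=1.0, s=2.0)
            for i in range(2)
        ] + [_score(1.0)]
        top = select_top_r(scores, 2)
        assert [t.subset.indices[0] for t in top] == [0, 1]

    def test_infinite_score_ranks_first(self):
        top = select_top_r([_score(2.0), _score(np.inf), _score(3.0)], 2)
        assert np.isinf(top[0].s) and top[1].s == 3.0

    def test_r_exceeding_h_rejected(self):
        with pytest.raises(ValueError):
            select_top_r([_score(1.0)], 2)

    def test_weight_ratios(self):
        np.testing.assert_allclose(
            compute_weights([_score(3.0), _score(1.0)]), [0.75, 0.25]
        )
        np.testing.assert_allclose(compute_weights([_score(1.0)]), [1.0])
        np.testing.assert_allclose(
            compute_weights([_score(2.0), _score(2.0), _score(1.0)]),
            [0.4, 0.4, 0.2],
        )

    def test_infinite_scores_take_uniform_mass(self):
        w = compute_weights([_score(np.inf), _score(5.0), _score(np.inf)])
        np.testing.assert_array_equal(w, [0.5, 0.0, 0.5])

    def test_all_zero_scores_fall_back_to_uniform(self, caplog):
        with caplog.at_level(logging.WARNING, logger="rkcnn.ensemble"):
            w = compute_weights([_score(0.0), _score(0.0)])
        np.testing.assert_array_equal(w, [0.5, 0.5])
        assert any("uniform" in rec.message for rec in caplog.records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([])


class TestFit:
    def test_degenerate_full_feature_single_subset(self, square_corners):
        model = rkcnn_fit(
            square_corners, RkCNNConfig(k=1, m=2, r=1, h=1, seed=0)
        )
        np.testing.assert_array_equal(
            model.selected[0].subset.indices, [0, 1]
        )
        np.testing.assert_array_equal(model.weights, [1.0])

    def test_h_equals_r_retains_every_draw(self):
        rng = np.random.default_rng(0)
        data = random_dataset(rng, q=10)
        model = rkcnn_fit(data, RkCNNConfig(k=1, m=3, r=8, h=8, seed=4))
        drawn = {tuple(s.indices) for s in sample_subsets(10, 3, 8, seed=4)}
        kept = {tuple(t.subset.indices) for t in model.selected}
        assert kept == drawn

    def test_fit_determinism(self):
        rng = np.random.default_rng(1)
        data = random_dataset(rng, q=12)
        cfg = RkCNNConfig(k=2, m=4, r=5, h=15, seed=11)
        m1, m2 = rkcnn_fit(data, cfg), rkcnn_fit(data, cfg)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        for a, b in zip(m1.selected, m2.selected):
            np.testing.assert_array_equal(a.subset.indices, b.subset.indices)

    def test_weights_sum_to_one_sorted_descending(self):
        rng = np.random.default_rng(2)
        data = random_dataset(rng, q=15)
        model = rkcnn_fit(data, RkCNNConfig(k=1, m=4, r=10, h=30, seed=3))
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.weights >= 0).all()
        s = [t.s for t in model.selected]
        assert all(a >= b for a, b in zip(s, s[1:]))

    def test_growing_h_never_lowers_minimum_retained_score(self):
        rng = np.random.default_rng(6)
        data = random_dataset(rng, q=20)
        mins = []
        for h in (5, 15, 40):
            model = rkcnn_fit(data, RkCNNConfig(k=1, m=4, r=5, h=h, seed=9))
            mins.append(model.selected[-1].s)
        assert mins[0] <= mins[1] <= mins[2]


class TestPredict:
    def test_single_subset_reduces_to_plain_kcnn(self):
        rng = np.random.default_rng(10)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = random_dataset(rng, n=12, q=5)
            queries = rng.normal(size=(4, data.q))
            k = int(rng.integers(1, 4))
            model = rkcnn_fit(
                data, RkCNNConfig(k=k, m=data.q, r=1, h=1, seed=seed)
            )
            np.testing.assert_array_equal(
                rkcnn_predict_proba(model, queries),
                kcnn_predict_proba_batch(data, queries, k),
            )
            np.testing.assert_array_equal(
                rkcnn_predict(model, queries),
                kcnn_predict_batch(data, queries, k),
            )

    def test_aggregate_is_convex_combination(self):
        rng = np.random.default_rng(21)
        data = random_dataset(rng, n_classes=3, q=10)
        model = rkcnn_fit(data, RkCNNConfig(k=1, m=3, r=6, h=18, seed=2))
        queries = rng.normal(size=(5, data.q))
        agg = rkcnn_predict_proba(model, queries)
        np.testing.assert_allclose(agg.sum(axis=1), 1.0, atol=1e-9)
        components = np.stack(
            [
                kcnn_predict_proba_batch(
                    Dataset(
                        data.features[:, t.subset.indices], data.labels
                    ),
                    queries[:, t.subset.indices],
                    model.config.k,
                )
                for t in model.selected
            ]
        )
        assert (agg <= components.max(axis=0) + 1e-12).all()
        assert (agg >= components.min(axis=0) - 1e-12).all()

    def test_dimension_mismatch_rejected(self, square_corners):
        model = rkcnn_fit(
            square_corners, RkCNNConfig(k=1, m=2, r=1, h=1, seed=0)
        )
        with pytest.raises(ValueError):
            rkcnn_predict(model, np.zeros((2, 3)))

    def test_estimator_wrapper_round_trip(self, separable_clouds):
        clf = RkCNN(k=1, m=2, r=5, h=15, seed=0).fit(separable_clouds)
        pred = clf.predict(separable_clouds.features)
        np.testing.assert_array_equal(pred, separable_clouds.labels)
        probs = clf.predict_proba(separable_clouds.features)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=0, m=1, r=1, h=1),
            dict(k=1, m=0, r=1, h=1),
            dict(k=1, m=1, r=0, h=1),
            dict(k=1, m=1, r=3, h=2),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RkCNNConfig(seed=0, **kwargs)
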