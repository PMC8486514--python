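import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from rbfrce import EnsembleConfig, fit_ensemble, predict
from rbfrce.bit_ensemble import (
    RandomBitLayer,
    boost_select_bits,
    bootstrap_split,
    make_random_bits,
)


class TestBootstrapSplit:
    @given(n=st.integers(1, 500), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition_property(self, n, seed):
        in_bag, oob = bootstrap_split(n, seed)
        assert len(in_bag) == n
        distinct = np.unique(in_bag)
        assert len(distinct) + len(oob) == n
        assert len(np.intersect1d(distinct, oob)) == 0

    def test_single_sample(self):
        in_bag, oob = bootstrap_split(1, seed=0)
        assert in_bag.tolist() == [0] and oob.size == 0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_split(0, seed=0)

    def test_deterministic(self):
        a = bootstrap_split(50, seed=7)
        b = bootstrap_split(50, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_oob_fraction_near_theory(self):
        # quick version; the acceptance suite runs the full 500-replicate check
        n = 1000
        fracs = [bootstrap_split(n, seed=s)[1].size / n for s in range(100)]
        assert np.mean(fracs) == pytest.approx((1 - 1 / n) ** n, abs=0.02)


class TestRandomBits:
    def test_deterministic_and_nontrivial(self):
        X = np.random.default_rng(0).standard_normal((40, 10))
        l1 = make_random_bits(X, 64, seed=3)
        l2 = make_random_bits(X, 64, seed=3)
        np.testing.assert_array_equal(l1.feature_idx, l2.feature_idx)
        np.testing.assert_array_equal(l1.weights, l2.weights)
        np.testing.assert_array_equal(l1.thresholds, l2.thresholds)
        bits = l1.transform(X)
        assert set(np.unique(bits)) == {0.0, 1.0}
        # threshold-at-quantile construction: every bit splits the train set
        means = bits.mean(axis=0)
        assert ((means > 0) & (means < 1)).all()

    def test_median_threshold_bit_balanced(self):
        X = np.random.default_rng(1).standard_normal((500, 3))
        layer = RandomBitLayer(
            feature_idx=np.array([[1, -1, -1]]),
            weights=np.array([[1.0, 0.0, 0.0]]),
            thresholds=np.array([np.median(X[:, 1])]),
        )
        mean = layer.transform(X).mean()
        assert 0.4 <= mean <= 0.6

    def test_pool_covers_every_feature(self):
        X = np.random.default_rng(2).standard_normal((30, 50))
        layer = make_random_bits(X, 256, seed=0)
        seen = set(layer.feature_idx.ravel().tolist()) - {-1}
        assert seen == set(range(50))

    def test_constant_matrix_drops_bits_with_warning(self):
        X = np.ones((20, 4))
        with pytest.warns(UserWarning, match="dropping bit"):
            layer = make_random_bits(X, 8, seed=0)
        assert layer.n_bits == 0


class TestBoostSelectBits:
    @staticmethod
    def _stump_logloss(col, y):
        """Independent oracle: exact minimized logistic loss of one stump."""

        def loss_for_leaf(mask):
            yy = y[mask]
            if len(yy) == 0:
                return 0.0
            res = minimize_scalar(
                lambda a: np.sum(np.log1p(np.exp(-(2 * yy - 1) * a))),
                bounds=(-10, 10), method="bounded",
            )
            return res.fun

        return loss_for_leaf(col > 0.5) + loss_for_leaf(col <= 0.5)

    def test_perfect_bit_selected_first(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=60)
        bits = (rng.random((60, 101)) > 0.5).astype(float)
        bits[:, 57] = y  # plant a perfect bit
        losses = [self._stump_logloss(bits[:, j], y) for j in range(101)]
        assert int(np.argmin(losses)) == 57  # oracle agrees it is the best
        assert boost_select_bits(bits, y, 5)[0] == 57

    def test_clamp_returns_all_bits(self):
        rng = np.random.default_rng(5)
        bits = (rng.random((20, 8)) > 0.5).astype(float)
        y = rng.integers(0, 2, size=20)
        assert boost_select_bits(bits, y, 100) == list(range(8))

    def test_tie_breaks_to_lowest_index(self):
        y = np.array([0, 0, 1, 1])
        col = np.array([0.0, 0.0, 1.0, 1.0])
        bits = np.column_stack([col, col, col])
        assert boost_select_bits(bits, y, 1)[0] == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            boost_select_bits(np.ones((4, 2)), np.zeros(4), 1)


class TestFitEnsemble:
    @pytest.mark.parametrize("learner", ["random_bits_forest", "plain_forest"])
    def test_separable_toy_high_oob_accuracy(self, separable_toy, learner):
        cfg = EnsembleConfig(
            n_trees=100, base_learner=learner, n_candidate_bits=256,
            n_selected_bits=64, seed=2,
        )
        ens = fit_ensemble(separable_toy, cfg)
        accs = [r.oob_accuracy for _, r in ens.trees if r.has_oob]
        assert np.mean(accs) >= 0.9

    def test_shuffled_labels_near_chance(self, separable_toy):
        rng = np.random.default_rng(0)
        from rbfrce import LabeledMatrix

        shuffled = LabeledMatrix(
            values=separable_toy.values,
            labels=rng.permutation(separable_toy.labels),
            feature_ids=separable_toy.feature_ids,
            sample_ids=separable_toy.sample_ids,
        )
        ens = fit_ensemble(shuffled, EnsembleConfig(n_trees=100, n_candidate_bits=128,
                                                    n_selected_bits=32, seed=3))
        accs = [r.oob_accuracy for _, r in ens.trees if r.has_oob]
        majority = max(np.mean(shuffled.labels == "a"), np.mean(shuffled.labels == "b"))
        assert abs(np.mean(accs) - majority) <= 0.15

    def test_refit_is_deterministic(self, separable_toy, fast_ensemble_config):
        e1 = fit_ensemble(separable_toy, fast_ensemble_config)
        e2 = fit_ensemble(separable_toy, fast_ensemble_config)
        a1 = [r.oob_accuracy for _, r in e1.trees]
        a2 = [r.oob_accuracy for _, r in e2.trees]
        assert a1 == a2
        np.testing.assert_array_equal(e1.selected_bits, e2.selected_bits)

    def test_row_order_invariance(self, separable_toy, fast_ensemble_config):
        from rbfrce import LabeledMatrix

        perm = np.random.default_rng(9).permutation(separable_toy.n_samples)
        shuffled = LabeledMatrix(
            values=separable_toy.values[perm],
            labels=separable_toy.labels[perm],
            feature_ids=separable_toy.feature_ids,
            sample_ids=separable_toy.sample_ids[perm],
        )
        e1 = fit_ensemble(separable_toy, fast_ensemble_config)
        e2 = fit_ensemble(shuffled, fast_ensemble_config)
        a1 = [r.oob_accuracy for _, r in e1.trees]
        a2 = [r.oob_accuracy for _, r in e2.trees]
        assert a1 == a2

    def test_too_few_samples_or_classes_rejected(self, separable_toy):
        from rbfrce import LabeledMatrix

        with pytest.raises(ValueError, match="classes"):
            fit_ensemble(
                LabeledMatrix(
                    values=np.random.rand(6, 2),
                    labels=np.array(["a"] * 6),
                    feature_ids=np.array(["f1", "f2"], dtype=object),
                    sample_ids=np.array([f"s{i}" for i in range(6)], dtype=object),
                ),
                EnsembleConfig(),
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EnsembleConfig(n_selected_bits=100, n_candidate_bits=50)


class TestPredict:
    def test_training_accuracy_on_separable(self, separable_toy, fast_ensemble_config):
        ens = fit_ensemble(separable_toy, fast_ensemble_config)
        pred = predict(ens, separable_toy.values)
        assert np.mean(pred == separable_toy.labels) >= 0.95

    def test_single_tree_vote_equals_tree(self, separable_toy):
        cfg = EnsembleConfig(n_trees=1, base_learner="plain_forest", seed=0)
        ens = fit_ensemble(separable_toy, cfg)
        tree, _ = ens.trees[0]
        direct = [ens.classes[int(c)] for c in tree.predict(separable_toy.values)]
        assert list(predict(ens, separable_toy.values)) == direct

    def test_feature_count_mismatch_rejected(self, separable_toy, fast_ensemble_config):
        ens = fit_ensemble(separable_toy, fast_ensemble_config)
        with pytest.raises(ValueError, match="features"):
            predict(ens, separable_toy.values[:, :1])

    def test_tie_goes_to_first_listed_class(self, separable_toy):
        # two trees that disagree everywhere -> every vote ties -> class "a"
        cfg = EnsembleConfig(n_trees=2, base_learner="plain_forest", seed=0)
        ens = fit_ensemble(separable_toy, cfg)

        class Stub:
            def __init__(self, c):
                self.c = c

            def predict(self, X):
                return np.full(len(X), self.c)

        ens.trees = [(Stub(0), ens.trees[0][1]), (Stub(1), ens.trees[1][1])]
        pred = predict(ens, separable_toy.values)
        assert set(pred) == {ens.classes[0]}
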