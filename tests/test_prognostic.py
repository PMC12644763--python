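"""Transformer predictor, AUC statistics, DeLong test, Shapley attribution."""

import itertools

import numpy as np
import pytest
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from sepstrat.prognostic import (
    ModelConfig,
    auc_score,
    build_model,
    delong_test,
    evaluate,
    published_config,
    shapley_attribution,
    train,
)

TINY = ModelConfig(layers=2, heads=2, token_dim=8, dropout=0.0,
                   epochs=0, batch_size=64, seed=0)


def _toy_data(n=200, f=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, f))
    y = (X[:, 0] - X[:, 1] + 0.5 * rng.normal(size=n) > 0).astype(int)
    return X, y


class TestArchitecture:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(token_dim=10, heads=4).validate()
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout=1.0).validate()

    def test_published_config_documents_published_budget(self):
        cfg = published_config()
        assert (cfg.layers, cfg.heads, cfg.epochs, cfg.batch_size) == (8, 8, 1400, 5000)
        assert cfg.learning_rate == pytest.approx(1e-3)
        assert cfg.dropout == pytest.approx(0.1)

    def test_softmax_outputs_normalized(self, rng):
        m = build_model(TINY, 4)
        probs, _ = m._forward(rng.normal(size=(17, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_token_sequence_length_is_features_plus_cls(self, rng):
        m = build_model(TINY, 6)
        _, cache = m._forward(rng.normal(size=(3, 6)))
        assert cache["h_final"].shape == (3, 7, TINY.token_dim)

    def test_same_seed_same_initial_weights(self):
        a, b = build_model(TINY, 4), build_model(TINY, 4)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(layers=2, heads=2, token_dim=4, dropout=0.0, epochs=0, seed=0)
        m = build_model(cfg, 3)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 3))
        y = rng.integers(0, 2, 5)

        def loss():
            probs, _ = m._forward(X)
            return -np.log(probs[np.arange(5), y] + 1e-12).mean()

        probs, cache = m._forward(X)
        grads = m._backward(probs, y, cache)
        eps = 1e-6
        for key in ["tok_W", "cls", "l0_Wq", "l0_bk", "l0_ln1_g", "l1_W2",
                    "l1_b3", "l0_Wo", "Wh1", "bh3", "lnf_g", "l1_ln2_b"]:
            arr = m.params[key]
            for idx in itertools.islice(np.ndindex(arr.shape), 3):
                orig = arr[idx]
                arr[idx] = orig + eps
                lp = loss()
                arr[idx] = orig - eps
                lm = loss()
                arr[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-3), key


class TestTraining:
    def test_zero_epochs_leaves_weights_unchanged(self):
        X, y = _toy_data()
        m = build_model(TINY, 4)
        before = {k: v.copy() for k, v in m.params.items()}
        m.fit(X, y)
        for k in before:
            np.testing.assert_array_equal(m.params[k], before[k])

    def test_loss_decreases_on_separable_data(self):
        X, y = _toy_data(400, seed=2)
        cfg = ModelConfig(layers=1, heads=2, token_dim=8, dropout=0.0,
                          epochs=20, batch_size=128, learning_rate=3e-3, seed=2)
        m = build_model(cfg, 4).fit(X, y)
        assert len(m.history) == 20
        assert m.history[-1] < m.history[0]

    def test_training_deterministic_given_seed(self):
        X, y = _toy_data(150, seed=3)
        cfg = ModelConfig(layers=1, heads=2, token_dim=8, dropout=0.1,
                          epochs=3, batch_size=64, seed=4)
        a = build_model(cfg, 4).fit(X, y)
        b = build_model(cfg, 4).fit(X, y)
        assert a.history == b.history

    def test_train_requires_min_class_counts(self, small_cohort):
        few = small_cohort[small_cohort["died_28d"] == 0].head(50).copy()
        few.loc[few.index[:5], "died_28d"] = 1
        m = build_model(TINY, 8)
        m.feature_names = list(small_cohort.columns[2:10])
        with pytest.raises(ValueError, match="20 rows"):
            train(m, few)


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        X, y = _toy_data(300, seed=5)
        cfg = ModelConfig(layers=1, heads=2, token_dim=8, dropout=0.0,
                          epochs=10, batch_size=128, seed=5)
        return build_model(cfg, 4).fit(X, y), X

    def test_duplicated_rows_identical_probabilities(self, fitted):
        m, X = fitted
        p = m.predict_proba(np.vstack([X[:1], X[:1]]))
        assert p[0] == p[1]

    def test_batch_invariance(self, fitted):
        m, X = fitted
        np.testing.assert_allclose(
            m.predict_proba(X, batch=7), m.predict_proba(X, batch=300), atol=1e-6
        )

    def test_row_order_invariance(self, fitted):
        m, X = fitted
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(
            m.predict_proba(X)[perm], m.predict_proba(X[perm]), atol=1e-9
        )

    def test_schema_mismatch_named(self, fitted):
        m, X = fitted
        with pytest.raises(ValueError, match="features"):
            m.predict_proba(X[:, :3])


class TestEvaluate:
    def test_perfect_separation_auc_one(self):
        assert auc_score([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_auc_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.normal(size=2000)
        assert abs(auc_score(s, y) - 0.5) < 0.05

    def test_auc_equals_pairwise_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 200))
            s = rng.choice(np.linspace(0, 1, 20), size=n)  # force ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            pos, neg = s[y == 1], s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            oracle = wins / (len(pos) * len(neg))
            assert auc_score(s, y) == pytest.approx(oracle, abs=1e-12)

    def test_auc_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        assert auc_score(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_metrics_consistent_with_confusion_counts(self):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        y = np.array([0, 0, 1, 1, 1, 0])
        m = evaluate(s, y, threshold_rule=0.5)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(1.0)
        assert m.accuracy == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.2], [1, 1])


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        s = rng.normal(size=100)
        res = delong_test(s, s, y)
        assert res.p_value == 1.0 and res.degenerate

    def test_swap_negates_z_keeps_p(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        a = rng.normal(size=300) + 0.8 * y
        b = rng.normal(size=300) + 0.3 * y
        r1 = delong_test(a, b, y)
        r2 = delong_test(b, a, y)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_auc_fields_match_rank_statistic(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        a = rng.normal(size=200) + y
        b = rng.normal(size=200)
        res = delong_test(a, b, y)
        assert res.auc_a == pytest.approx(auc_score(a, y), abs=1e-12)
        assert res.auc_b == pytest.approx(auc_score(b, y), abs=1e-12)

    def test_variance_positive_for_distinct_placements(self, rng):
        y = np.array([0, 1] * 50)
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        assert not delong_test(a, b, y).degenerate


class TestShapley:
    def test_local_accuracy_exact_identity(self, rng):
        f = lambda X: expit(X @ np.array([1.0, -2.0, 0.5]))
        Xe = rng.normal(size=(4, 3))
        Xb = rng.normal(size=(50, 3))
        res = shapley_attribution(f, Xe, Xb, n_permutations=16, seed=0)
        np.testing.assert_allclose(
            res.values.sum(axis=1), res.predictions - res.baseline, atol=1e-10
        )

    def test_dummy_feature_gets_zero_attribution(self, rng):
        f = lambda X: X[:, 0] * 1.0  # ignores features 1 and 2
        Xe = rng.normal(size=(3, 3))
        Xb = rng.normal(size=(100, 3))
        res = shapley_attribution(f, Xe, Xb, n_permutations=64, seed=1)
        np.testing.assert_allclose(res.values[:, 1:], 0.0, atol=1e-10)

    def test_additive_model_closed_form(self, rng):
        f = lambda X: X[:, 0] + X[:, 1]
        Xe = rng.normal(size=(5, 2))
        Xb = rng.normal(size=(400, 2))
        res = shapley_attribution(f, Xe, Xb, n_permutations=200, seed=2)
        expected = Xe - Xb.mean(axis=0)
        assert np.abs(res.values - expected).max() < 4 * res.stderr.max() + 0.05

    def test_ranking_stable_across_seeds(self, rng):
        f = lambda X: 3.0 * X[:, 2] + 0.2 * X[:, 0]
        Xe = rng.normal(size=(1, 4)) + 1.0
        Xb = rng.normal(size=(100, 4))
        tops = {
            int(np.argmax(np.abs(
                shapley_attribution(f, Xe, Xb, n_permutations=32, seed=s).values[0]
            )))
            for s in range(5)
        }
        assert tops == {2}

    def test_schema_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="schema"):
            shapley_attribution(lambda X: X[:, 0], rng.normal(size=(2, 3)),
                                rng.normal(size=(5, 4)))
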