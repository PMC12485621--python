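"""One-vs-rest experts, attention fusion, meta-network, end-to-end model."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from ystr_ancestry.base import BinaryClassifierSpec
from ystr_ancestry.features import build_vocabulary
from ystr_ancestry.metanet import MetaNetworkConfig, train_meta_network
from ystr_ancestry.ovr import (
    AttentionWeights,
    FitError,
    OvRAttentionModel,
    OvRPrediction,
    compute_attention_weights,
    count_classifiers,
    fit_ovr,
    fuse,
)
from ystr_ancestry.preprocess import LabelEncoding, stratified_split
from ystr_ancestry.simulate import (
    SimulationConfig,
    generate_table,
    separable_models,
)

SPEC = BinaryClassifierSpec("logistic_regression", seed=0)
FAST_META = MetaNetworkConfig(hidden_sizes=(16, 8), epochs=200, learning_rate=0.01, seed=0)


def separable_setup(panel, k=3, n=60, seed=0):
    models = separable_models(panel, k, seed=seed)
    table = generate_table(SimulationConfig(
        panel, models, {m.name: n for m in models}, seed=seed))
    return table


class TestCountClassifiers:
    @pytest.mark.parametrize(
        "k, strategy, expected",
        [(7, "ovr", 7), (7, "ovo", 21), (2, "ovo", 1), (2, "ovr", 2),
         (10, "ovo", 45)],
    )
    def test_counts(self, k, strategy, expected):
        assert count_classifiers(k, strategy) == expected

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            count_classifiers(1, "ovr")


class TestAttention:
    def test_equal_experts_uniform(self):
        w = compute_attention_weights([0.8] * 5, [0.1] * 5)
        assert np.allclose(w.weights, 0.2)

    def test_low_temperature_approaches_argmax(self):
        w = compute_attention_weights([0.9, 0.6, 0.6], [0, 0, 0],
                                      temperature=1e-3)
        assert w.weights[0] > 0.999

    def test_softmax_arithmetic(self):
        m = np.array([0.9, 0.6, 0.6])
        w = compute_attention_weights(m, [0, 0, 0], temperature=1.0)
        e = np.exp(m - m.max())
        assert np.allclose(w.weights, e / e.sum(), atol=1e-12)

    def test_normalization_for_any_input(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            k = rng.integers(1, 9)
            w = compute_attention_weights(rng.normal(size=k),
                                          rng.uniform(0, 1, k),
                                          temperature=float(rng.uniform(0.1, 5)))
            assert np.all(w.weights >= 0)
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bad_temperature(self):
        with pytest.raises(ValueError):
            compute_attention_weights([1.0], [0.0], temperature=0.0)

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            AttentionWeights(np.array([0.5, 0.6]))


class TestFuse:
    def _pred(self, probs):
        probs = np.atleast_2d(probs)
        names = tuple(f"P{i}" for i in range(probs.shape[1]))
        return OvRPrediction(probs=probs, classifier_order=names)

    def test_uniform_weights_give_arithmetic_mean(self):
        probs = np.array([[0.9, 0.1, 0.4], [0.2, 0.5, 0.8]])
        w = AttentionWeights(np.full(3, 1 / 3))
        fused = fuse(self._pred(probs), w)
        assert np.allclose(fused[:, -1], probs.mean(axis=1), atol=1e-12)

    def test_one_hot_weight_selects_single_expert(self):
        probs = np.array([[0.9, 0.1, 0.4]])
        w = AttentionWeights(np.array([0.0, 1.0, 0.0]))
        fused = fuse(self._pred(probs), w)
        assert fused[0, -1] == pytest.approx(0.1, abs=1e-15)

    def test_weighted_sum_arithmetic(self):
        probs = np.array([[0.9, 0.1, 0.4]])
        w = AttentionWeights(np.array([0.5, 0.3, 0.2]))
        fused = fuse(self._pred(probs), w)
        assert fused[0, -1] == pytest.approx(0.56, abs=1e-12)
        assert np.allclose(fused[0, :3], [0.45, 0.03, 0.08], atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            fuse(self._pred([[0.5, 0.5]]), AttentionWeights(np.array([1.0])))


class TestFitOvr:
    def _fit(self, panel, k, n=60, seed=0):
        table = separable_setup(panel, k, n, seed)
        enc = LabelEncoding.from_names(set(table.populations))
        vocab = build_vocabulary(table)
        from ystr_ancestry.features import one_hot_encode
        X = one_hot_encode(table, vocab).values.astype(float)
        y = enc.encode(table.populations)
        specs = {c: SPEC for c in enc.classes}
        return fit_ovr(X, y, enc, specs, seed=seed)

    def test_one_expert_per_class(self, small_panel):
        experts, _ = self._fit(small_panel, 3)
        assert len(experts) == 3

    def test_two_class_degenerate(self, small_panel):
        experts, _ = self._fit(small_panel, 2)
        assert len(experts) == 2

    def test_disjoint_support_experts_perfect(self, small_panel):
        experts, _ = self._fit(small_panel, 3)
        for e in experts:
            assert e.oof_balanced_accuracy == pytest.approx(1.0)

    def test_absent_class_rejected(self, small_panel):
        table = separable_setup(small_panel, 2)
        enc = LabelEncoding.from_names({"POP1", "POP2", "GHOST"})
        vocab = build_vocabulary(table)
        from ystr_ancestry.features import one_hot_encode
        X = one_hot_encode(table, vocab).values.astype(float)
        y = enc.encode(table.populations)
        with pytest.raises(FitError, match="GHOST"):
            fit_ovr(X, y, enc, {c: SPEC for c in enc.classes})


class TestMetaNetwork:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (90, 4))
        y = rng.integers(0, 3, 90)
        net = train_meta_network(X, y, FAST_META)
        probs = net.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (60, 3))
        y = rng.integers(0, 2, 60)
        p1 = train_meta_network(X, y, FAST_META).predict_proba(X)
        p2 = train_meta_network(X, y, FAST_META).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_capacity_on_separable_features(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, 150)
        X = np.eye(3)[y] + rng.normal(0, 0.05, (150, 3))
        cfg = MetaNetworkConfig(hidden_sizes=(16, 8), epochs=200, seed=0)
        net = train_meta_network(X, y, cfg)
        assert np.mean(net.predict(X) == y) == 1.0


class TestEndToEnd:
    def _results(self, panel, seed=0):
        table = separable_setup(panel, 3, n=60, seed=seed)
        split = stratified_split(table, 0.8, seed)
        model = OvRAttentionModel(
            split.train,
            specs={p: SPEC for p in set(split.train.populations)},
            meta_config=FAST_META,
            vocab=build_vocabulary(table),
            seed=seed,
        )
        return model.fit(), split

    def test_probabilities_sum_to_one(self, small_panel):
        results, split = self._results(small_panel)
        probs = results.predict_proba(split.test)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_test_accuracy_perfect(self, small_panel):
        results, split = self._results(small_panel)
        predicted = results.predict(split.test)
        assert predicted == list(split.test.populations)

    def test_permutation_invariance(self, small_panel):
        results, split = self._results(small_panel)
        table = split.test
        perm = list(reversed(range(len(table))))
        probs_fwd = results.predict_proba(table)
        probs_rev = results.predict_proba(table.subset(perm))
        assert np.allclose(probs_fwd[perm], probs_rev, atol=1e-12)

    def test_uniform_attention_linear_meta_matches_mean_argmax(self, small_panel):
        # with uniform weights and a linear softmax combiner the stack
        # should agree with argmax of the mean calibrated probabilities
        # on cleanly separable data
        results, split = self._results(small_panel)
        pred = results.ovr_probabilities(split.test)
        uniform = AttentionWeights(np.full(results.k, 1 / results.k))
        fused = fuse(pred, uniform)
        train_pred = results.ovr_probabilities(results.model.table)
        train_fused = fuse(train_pred, uniform)
        y_train = results.encoding.encode(results.model.table.populations)
        linear = LogisticRegression(max_iter=5000).fit(train_fused, y_train)
        stack_argmax = linear.predict(fused)
        mean_argmax = np.argmax(pred.probs, axis=1)
        assert np.array_equal(stack_argmax, mean_argmax)

    def test_summary_mentions_every_population(self, small_panel):
        results, _ = self._results(small_panel)
        text = results.summary()
        for name in results.encoding.classes:
            assert name in text

    def test_predict_report_top2(self, small_panel):
        results, split = self._results(small_panel)
        df = results.predict_report(split.test, top_n=2)
        assert {"SampleID", "Predicted", "Top1", "Top1_prob", "Top2",
                "Top2_prob"} <= set(df.columns)
        assert (df["Top1_prob"] >= df["Top2_prob"]).all()
        assert (df["Predicted"] == df["Top1"]).all()
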