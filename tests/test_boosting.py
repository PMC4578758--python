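import numpy as np
import pytest

from hdboost import (AdaBoostM1Classifier, AdaBoostM1ICVClassifier,
                     BoostConfig, GradientExpBoostClassifier, LabeledDataset,
                     LogitBoostClassifier, SimulationConfig,
                     fit_adaboost_m1, fit_grboost, fit_st_grboost,
                     model_from_json, model_to_json, simulate_block_mvn,
                     simulate_null_independent, staged_predict)
from hdboost.boosting import (W_MIN, adaboost_weight_update,
                              stratified_folds)


@pytest.fixture
def noisy_xor_free():
    """A small separable-with-noise two-feature problem (40 samples)."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 5))
    y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.standard_normal(40) > 0,
                 2, 1)
    if len(np.unique(y)) < 2:  # pragma: no cover
        raise RuntimeError("bad fixture draw")
    return LabeledDataset(X, y)


class TestAdaBoostWeightUpdate:
    def test_quarter_error_update(self):
        # 4 samples, uniform weights, 1 misclassified:
        # eps = 1/4, alpha = ln 3, misclassified weight -> 0.5
        w = np.full(4, 0.25)
        eps_i = np.array([1.0, 0.0, 0.0, 0.0])
        eps, alpha, w_new = adaboost_weight_update(w, eps_i)
        assert eps == pytest.approx(0.25)
        assert alpha == pytest.approx(np.log(3.0))
        np.testing.assert_allclose(w_new, [0.5, 1 / 6, 1 / 6, 1 / 6])
        assert w_new.sum() == pytest.approx(1.0)

    def test_zero_error_clamps_alpha_and_freezes_weights(self):
        w = np.full(10, 0.1)
        eps, alpha, w_new = adaboost_weight_update(w, np.zeros(10))
        delta = 1.0 / 20.0
        assert alpha == pytest.approx(np.log((1 - delta) / delta))
        np.testing.assert_array_equal(w_new, w)

    def test_half_error_gives_zero_alpha(self):
        w = np.full(4, 0.25)
        eps_i = np.array([1.0, 1.0, 0.0, 0.0])
        eps, alpha, w_new = adaboost_weight_update(w, eps_i)
        assert alpha == pytest.approx(0.0)
        np.testing.assert_allclose(w_new, w)

    def test_fractional_icv_indicators_hand_oracle(self):
        # hand-executed update with cross-validated indicators on 5 samples
        w = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        eps_i = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        eps, alpha, w_new = adaboost_weight_update(w, eps_i)
        assert eps == pytest.approx(0.4)
        assert alpha == pytest.approx(np.log(0.6 / 0.4))
        expected = w * np.exp(alpha * eps_i)
        expected /= expected.sum()
        np.testing.assert_allclose(w_new, expected)


class TestAdaBoostM1:
    def test_zero_resub_error_ensemble_equals_base_tree(self):
        # p >> n null data: every stage has zero resubstitution error, the
        # weights freeze, and the ensemble is bit-identical to one tree
        data = simulate_null_independent(p=10000, n=50, seed=1)
        model = AdaBoostM1Classifier(n_estimators=8, max_depth=5)
        model.fit(data.X, data.y)
        assert (model.errors_ == 0.0).all()
        base_pred = model.estimators_[0].predict(data.X)
        for pred in model.staged_predict(data.X):
            np.testing.assert_array_equal(pred, base_pred)

    def test_stump_boosting_beats_single_stump(self, noisy_xor_free):
        d = noisy_xor_free
        model = AdaBoostM1Classifier(n_estimators=50, max_depth=1)
        model.fit(d.X, d.y)
        stump_err = np.mean(
            next(iter(model.staged_predict(d.X))) != d.y)
        final_err = np.mean(model.predict(d.X) != d.y)
        assert final_err <= stump_err

    def test_weights_normalized_every_iteration(self, noisy_xor_free):
        # run the recursion manually through the public update helper
        d = noisy_xor_free
        model = AdaBoostM1Classifier(n_estimators=20, max_depth=1)
        model.fit(d.X, d.y)
        assert np.isfinite(model.alphas_).all()
        assert (model.alphas_ >= 0).all()
        assert (model.errors_ >= 0).all() and (model.errors_ <= 1.0).all()

    def test_one_class_input_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            AdaBoostM1Classifier(n_estimators=2).fit(X, np.ones(4))

    def test_zero_iterations_rejected(self, noisy_xor_free):
        with pytest.raises(ValueError):
            AdaBoostM1Classifier(n_estimators=0).fit(
                noisy_xor_free.X, noisy_xor_free.y)

    def test_wrapper_and_determinism(self, noisy_xor_free):
        cfg = BoostConfig(M=10, seed=3)
        a = fit_adaboost_m1(noisy_xor_free, cfg)
        b = fit_adaboost_m1(noisy_xor_free, cfg)
        np.testing.assert_array_equal(a.alphas_, b.alphas_)
        np.testing.assert_array_equal(a.predict(noisy_xor_free.X),
                                      b.predict(noisy_xor_free.X))


class TestAdaBoostM1ICV:
    def test_perfectly_cv_predictable_data_freezes_weights(self):
        # wide class separation: every fold model classifies the held-out
        # samples perfectly, so eps_i = 0 and the ensemble repeats one tree
        X = np.vstack([np.full((10, 3), -5.0), np.full((10, 3), 5.0)])
        X += np.random.default_rng(2).normal(0, 0.1, X.shape)
        y = np.repeat([1, 2], 10)
        model = AdaBoostM1ICVClassifier(n_estimators=5, max_depth=1,
                                        icv_folds=5)
        model.fit(X, y)
        assert (model.errors_ == 0.0).all()
        preds = list(model.staged_predict(X))
        for p in preds[1:]:
            np.testing.assert_array_equal(p, preds[0])

    def test_icv_updates_weights_when_m1_freezes(self):
        # on overfit-prone data AdaBoost.M1 freezes (eps=0) but the ICV
        # variant sees nonzero cross-validated error and moves its weights
        train, _ = simulate_block_mvn(SimulationConfig(seed=8))
        m1 = AdaBoostM1Classifier(n_estimators=3, max_depth=5)
        m1.fit(train.X, train.y)
        icv = AdaBoostM1ICVClassifier(n_estimators=3, max_depth=5,
                                      random_state=0)
        icv.fit(train.X, train.y)
        assert (m1.errors_ == 0.0).all()
        assert (icv.errors_ > 0.0).any()

    def test_too_many_folds_rejected(self, noisy_xor_free):
        model = AdaBoostM1ICVClassifier(n_estimators=2, icv_folds=100)
        with pytest.raises(ValueError):
            model.fit(noisy_xor_free.X, noisy_xor_free.y)

    def test_stratified_folds_partition_and_balance(self):
        y = np.repeat([1, 2], [12, 8])
        rng = np.random.default_rng(0)
        folds = stratified_folds(y, 5, rng)
        flat = np.concatenate(folds)
        assert sorted(flat) == list(range(20))
        for f in folds:
            # 12/5 and 8/5 per fold, rounded: sizes 4 each, both classes
            assert np.isin(1, y[f]) and np.isin(2, y[f])


class TestGradientBoosting:
    def test_newton_step_single_node(self):
        # residuals {1, -1, 1} in one node -> gamma = 1/3
        X = np.zeros((3, 1))
        r = np.array([1.0, -1.0, 1.0])
        from hdboost.tree import fit_regression_tree
        tree = fit_regression_tree(X, r)
        GradientExpBoostClassifier._newton_leaves(tree, X, r)
        assert tree.predict(X)[0] == pytest.approx(1 / 3)

    def test_balanced_data_f0_zero(self, noisy_xor_free):
        train, _ = simulate_block_mvn(SimulationConfig(p=100, n_train=20,
                                                       n_de=100,
                                                       n_test_per_class=5,
                                                       seed=0))
        model = GradientExpBoostClassifier(n_estimators=2).fit(train.X,
                                                               train.y)
        assert model.F0_ == pytest.approx(0.0)

    def test_tiny_learning_rate_predicts_majority(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        y = np.repeat([1, 2], [10, 20])  # majority class 2 -> F0 > 0
        model = GradientExpBoostClassifier(n_estimators=3,
                                           learning_rate=1e-12)
        model.fit(X, y)
        assert (model.predict(X) == 2).all()

    def test_training_loss_nonincreasing(self, noisy_xor_free):
        d = noisy_xor_free
        model = GradientExpBoostClassifier(n_estimators=30, max_depth=2)
        model.fit(d.X, d.y)
        assert (np.diff(model.train_loss_) <= 1e-12).all()

    def test_subsample_one_identical_to_plain(self, noisy_xor_free):
        d = noisy_xor_free
        a = GradientExpBoostClassifier(n_estimators=10, subsample=1.0,
                                       random_state=9).fit(d.X, d.y)
        b = fit_grboost(d, BoostConfig(M=10, seed=9))
        for ta, tb in zip(a.estimators_, b.estimators_):
            np.testing.assert_array_equal(ta.feature, tb.feature)
            np.testing.assert_allclose(ta.value, tb.value)
        np.testing.assert_allclose(a.decision_function(d.X),
                                   b.decision_function(d.X))

    def test_subsample_size_and_oob_record(self):
        train, _ = simulate_block_mvn(SimulationConfig(p=100, n_train=50,
                                                       n_de=100,
                                                       n_test_per_class=5,
                                                       seed=1))
        model = fit_st_grboost(LabeledDataset(train.X, train.y),
                               BoostConfig(M=5, eta=0.5, seed=2))
        assert model.subsample == 0.5
        assert model.oob_improvement_.shape == (5,)
        # eta=0.5 of n=50 -> each tree sees exactly 25 samples: its leaf
        # sample counts cannot exceed 25 in any stage (checked via apply)
        counts = np.bincount(model.estimators_[0].apply(train.X))
        assert counts.sum() == 50  # routing covers everyone at predict time

    def test_staged_scores_are_prefix_sums(self, noisy_xor_free):
        d = noisy_xor_free
        model = GradientExpBoostClassifier(n_estimators=6, learning_rate=0.3,
                                           max_depth=2).fit(d.X, d.y)
        F = np.full(d.n_samples, model.F0_)
        staged = list(model.staged_decision_function(d.X))
        for m, tree in enumerate(model.estimators_):
            F = F + 0.3 * tree.predict(d.X)
            np.testing.assert_allclose(staged[m], F)


class TestLogitBoost:
    def test_first_iteration_working_response(self):
        # from p = 1/2: z = +/-2 exactly, w = 1/4
        p = np.full(6, 0.5)
        ystar = np.array([1.0, 0, 1, 0, 1, 0])
        w = np.maximum(p * (1 - p), W_MIN)
        z = (ystar - p) / w
        np.testing.assert_allclose(w, 0.25)
        np.testing.assert_allclose(z, np.where(ystar == 1, 2.0, -2.0))

    def test_deviance_decreases_on_separable_data(self, noisy_xor_free):
        d = noisy_xor_free
        model = LogitBoostClassifier(n_estimators=20).fit(d.X, d.y)
        ystar = (d.y == 2).astype(float)
        nll = []
        for F in model.staged_decision_function(d.X):
            p = 1 / (1 + np.exp(-2 * F))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            nll.append(-np.mean(ystar * np.log(p)
                                + (1 - ystar) * np.log(1 - p)))
        assert nll[4] < nll[0]

    def test_predict_proba_matches_decision_function(self, noisy_xor_free):
        d = noisy_xor_free
        model = LogitBoostClassifier(n_estimators=5).fit(d.X, d.y)
        F = model.decision_function(d.X)
        proba = model.predict_proba(d.X)
        np.testing.assert_allclose(proba[:, 1], 1 / (1 + np.exp(-2 * F)))
        assert proba.sum(axis=1) == pytest.approx(1.0)


class TestStagedPredictAndSerialization:
    @pytest.mark.parametrize("cls,kwargs", [
        (AdaBoostM1Classifier, {"max_depth": 1}),
        (GradientExpBoostClassifier, {"max_depth": 2, "subsample": 0.8}),
        (LogitBoostClassifier, {}),
    ])
    def test_full_staged_equals_predict(self, noisy_xor_free, cls, kwargs):
        d = noisy_xor_free
        model = cls(n_estimators=7, random_state=1, **kwargs).fit(d.X, d.y)
        labels, scores = staged_predict(model, d.X, [3, 7])
        np.testing.assert_array_equal(labels[1], model.predict(d.X))
        np.testing.assert_allclose(scores[1], model.decision_function(d.X))

    def test_out_of_range_iteration_rejected(self, noisy_xor_free):
        d = noisy_xor_free
        model = LogitBoostClassifier(n_estimators=3).fit(d.X, d.y)
        with pytest.raises(ValueError):
            staged_predict(model, d.X, [4])

    @pytest.mark.parametrize("cls,kwargs", [
        (AdaBoostM1Classifier, {"max_depth": 2}),
        (AdaBoostM1ICVClassifier, {"max_depth": 1, "icv_folds": 4}),
        (GradientExpBoostClassifier, {"subsample": 0.9, "max_depth": 2}),
        (LogitBoostClassifier, {}),
    ])
    def test_json_round_trip_bit_identical(self, noisy_xor_free, cls,
                                           kwargs):
        d = noisy_xor_free
        model = cls(n_estimators=4, random_state=5, **kwargs).fit(d.X, d.y)
        clone = model_from_json(model_to_json(model))
        X_new = np.random.default_rng(6).standard_normal((25, 5))
        np.testing.assert_array_equal(model.predict(X_new),
                                      clone.predict(X_new))
        np.testing.assert_allclose(model.decision_function(X_new),
                                   clone.decision_function(X_new))
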