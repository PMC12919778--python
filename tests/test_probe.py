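import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from flens import (
    EmbeddingSet,
    LinearProbe,
    ProbeConfig,
    VariableSpec,
    cohen_kappa,
    evaluate_probe,
    subsample_experiment,
    train_probe,
)
from flens.probe import bootstrap_metrics, confusion_matrix

SITE = VariableSpec("site")


def _labeled_set(X, labels, var="site", ids=None):
    ids = ids or [f"i{k}" for k in range(len(X))]
    return EmbeddingSet(ids, X, pd.DataFrame({var: labels}))


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(np.array([[10, 0], [0, 10]])) == pytest.approx(1.0)

    def test_formula_example(self):
        # p_o = 0.7, p_e = (25*30 + 25*20) / 50**2 = 0.5 -> kappa = 0.4
        assert cohen_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)

    def test_constant_predictor_is_zero(self):
        # p_o = p_e = 0.6
        assert cohen_kappa(np.array([[15, 0], [10, 0]])) == pytest.approx(0.0)

    def test_undefined_when_expected_agreement_is_one(self):
        assert cohen_kappa(np.array([[5, 0], [0, 0]])) is None

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(np.zeros((2, 2)))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(2, 6)
            C = rng.integers(0, 30, size=(m, m))
            C[0, 0] += 1  # ensure non-degenerate
            perm = rng.permutation(m)
            assert cohen_kappa(C[np.ix_(perm, perm)]) == pytest.approx(
                cohen_kappa(C)
            )

    def test_matches_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y_t = rng.integers(0, 4, 100).astype(str)
            y_p = rng.integers(0, 4, 100).astype(str)
            C = confusion_matrix(y_t, y_p, ["0", "1", "2", "3"])
            assert cohen_kappa(C) == pytest.approx(
                cohen_kappa_score(y_t, y_p), abs=1e-12
            )


class TestLinearProbe:
    def test_separable_classes_learned(self):
        rng = np.random.default_rng(0)
        X = np.concatenate(
            [rng.normal(-5, 0.1, 100), rng.normal(5, 0.1, 100)]
        )[:, None]
        y = ["neg"] * 100 + ["pos"] * 100
        model = LinearProbe(random_state=0).fit(X, y)
        Xf = np.concatenate(
            [rng.normal(-5, 0.1, 500), rng.normal(5, 0.1, 500)]
        )[:, None]
        yf = np.array(["neg"] * 500 + ["pos"] * 500)
        assert (model.predict(Xf) == yf).mean() >= 0.99

    def test_no_signal_stays_near_chance(self):
        # identical features for every item: accuracy can only be chance
        X = np.ones((300, 8))
        y = np.array(["a", "b"] * 150)
        model = LinearProbe(random_state=1).fit(X[:200], y[:200])
        acc = (model.predict(X[200:]) == y[200:]).mean()
        assert 0.35 <= acc <= 0.65

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 6))
        y = rng.choice(["a", "b", "c"], 150)
        m1 = LinearProbe(random_state=7).fit(X, y)
        m2 = LinearProbe(random_state=7).fit(X, y)
        assert np.array_equal(m1.coef_, m2.coef_)
        assert np.array_equal(m1.intercept_, m2.intercept_)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            LinearProbe().fit(np.zeros((5, 2)), ["a"] * 5)

    def test_missing_variable_rejected(self, small_set):
        with pytest.raises(KeyError, match="stage"):
            train_probe(small_set, VariableSpec("stage"))

    def test_classes_sorted_lexicographically(self):
        X = np.random.default_rng(0).normal(size=(30, 3))
        y = ["zeta", "alpha", "mid"] * 10
        model = LinearProbe(epochs=1).fit(X, y)
        assert model.classes_.tolist() == ["alpha", "mid", "zeta"]

    def test_sklearn_get_set_params(self):
        p = LinearProbe(epochs=3)
        assert p.get_params()["epochs"] == 3
        p.set_params(learning_rate=0.01)
        assert p.learning_rate == 0.01


class TestEvaluateProbe:
    def test_all_correct_predictions(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 0.1, 100),
                            rng.normal(5, 0.1, 100)])[:, None]
        y = ["neg"] * 100 + ["pos"] * 100
        es = _labeled_set(X, y)
        model = train_probe(es, SITE)
        Xt = np.array([[-5.0]] * 25 + [[5.0]] * 25)
        test = _labeled_set(Xt, ["neg"] * 25 + ["pos"] * 25)
        res = evaluate_probe(model, test, SITE)
        assert res.accuracy == 1.0
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)
        assert res.kappa_mean == pytest.approx(1.0)
        assert res.per_class_accuracy == {"neg": 1.0, "pos": 1.0}

    def test_accuracy_equals_confusion_trace(self, strong_batch_set):
        from flens import patient_disjoint_split, subset

        split = patient_disjoint_split(strong_batch_set, seed=0,
                                       stratify_by="site")
        tr = subset(strong_batch_set, split.ids_in("train"))
        te = subset(strong_batch_set, split.ids_in("test"))
        cfg = ProbeConfig(n_bootstrap=10, seed=0)
        res = evaluate_probe(train_probe(tr, SITE, cfg), te, SITE, cfg)
        assert res.accuracy == np.trace(res.confusion) / res.n_test
        assert res.confusion.sum() == res.n_test

    def test_constant_predictor_kappa_zero_every_replicate(self):
        # model that always outputs one class: kappa = 0 per replicate
        y_true = np.array(["a", "b"] * 50, dtype=object)
        y_pred = np.array(["a"] * 100, dtype=object)
        _, kappas = bootstrap_metrics(y_true, y_pred, ["a", "b"], 50, seed=0)
        assert all(k == pytest.approx(0.0) for k in kappas)

    def test_empty_test_rejected(self, small_set):
        model = LinearProbe(epochs=1).fit(
            np.zeros((4, 4)), ["a", "a", "b", "b"]
        )
        empty = EmbeddingSet([], np.empty((0, 4)),
                             pd.DataFrame({"site": []}))
        with pytest.raises(ValueError, match="empty"):
            evaluate_probe(model, empty, SITE)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        y_true = rng.choice(["a", "b", "c"], 300)
        y_pred = np.where(rng.random(300) < 0.6, y_true,
                          rng.choice(["a", "b", "c"], 300))
        accs, _ = bootstrap_metrics(y_true, y_pred, ["a", "b", "c"], 200, 0)
        lo, hi = np.percentile(accs, [2.5, 97.5])
        assert lo <= np.median(accs) <= hi


class TestSubsampleExperiment:
    def test_full_fraction_single_repeat_matches_plain_run(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4)) + np.repeat([[0], [3]], 50, 0)
        es = _labeled_set(X, ["a"] * 50 + ["b"] * 50)
        test = _labeled_set(rng.normal(size=(40, 4)) +
                            np.repeat([[0], [3]], 20, 0),
                            ["a"] * 20 + ["b"] * 20)
        cfg = ProbeConfig(n_bootstrap=10, seed=9)
        table = subsample_experiment(es, test, SITE, [1.0], 1, cfg)
        seed_full = int(np.random.default_rng(9).integers(0, 2**31 - 1,
                                                          size=(1, 1))[0, 0])
        cfg_full = ProbeConfig(n_bootstrap=10, seed=seed_full)
        plain = evaluate_probe(train_probe(es, SITE, cfg_full), test, SITE,
                               cfg_full)
        assert table.mean_accuracy.iloc[0] == pytest.approx(plain.accuracy)
        assert table.sd.iloc[0] == 0.0

    def test_tiny_fraction_emptying_a_class_rejected(self):
        rng = np.random.default_rng(0)
        es = _labeled_set(rng.normal(size=(100, 3)),
                          [f"s{k % 5}" for k in range(100)])
        with pytest.raises(ValueError, match="empty"):
            subsample_experiment(es, es, SITE, [0.001], 1,
                                 ProbeConfig(n_bootstrap=5))

    def test_unsorted_fractions_rejected(self, small_set):
        with pytest.raises(ValueError, match="sorted"):
            subsample_experiment(small_set, small_set, SITE, [1.0, 0.5], 1)
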