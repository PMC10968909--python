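"""Base learners, TPE hyperparameter search and the stacked ensemble."""

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from plistack.metrics import confusion_counts, f1_macro
from plistack.models import (
    MODEL_NAMES,
    SEARCH_SPACES,
    ParamSpec,
    SearchSpace,
    feature_importances,
    fit_model,
    fit_stack,
    importance_ranking,
    make_model,
    tune,
)

N_EST = 40  # scaled-down boosting rounds for unit tests


def _blobs(n=240, d=8, informative=1, sep=4.0, seed=0):
    """3-class data where only the first `informative` features matter."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, size=n)
    X = rng.standard_normal((n, d))
    for k in range(informative):
        X[:, k] += sep * (y - 1)
    return X, np.array(["HC", "GAD", "DD"])[y]


class TestBaseLearners:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_fit_predict_and_importances(self, name):
        X, y = _blobs(seed=1)
        classes, y_enc = np.unique(y, return_inverse=True)
        model = make_model(name, seed=0, n_estimators=N_EST)
        fit_model(name, model, X, y_enc)
        assert (model.predict(X) == y_enc).mean() > 0.9
        imp = feature_importances(name, model)
        assert imp.shape == (8,)
        assert imp.sum() == pytest.approx(1.0)
        assert np.argmax(imp) == 0  # the only informative feature

    def test_importance_ranking_tie_break(self):
        imp = np.array([0.2, 0.5, 0.2, 0.1])
        assert importance_ranking(imp).tolist() == [1, 0, 2, 3]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            make_model("randomforest")


class TestTune:
    def test_trial_count_and_determinism(self):
        X, y = _blobs(seed=2)
        best1, trials1 = tune("lightgbm", X, y, n_trials=12, seed=3,
                              n_estimators=N_EST)
        best2, trials2 = tune("lightgbm", X, y, n_trials=12, seed=3,
                              n_estimators=N_EST)
        assert len(trials1) == 12
        assert best1 == best2
        assert [t["params"] for t in trials1] == [t["params"] for t in trials2]

    def test_collapsed_space_returns_point(self):
        X, y = _blobs(seed=4)
        point = SearchSpace("lightgbm", (
            ParamSpec("num_leaves", "int", 31, 31),
            ParamSpec("learning_rate", "loguniform", 0.05, 0.05),
        ))
        best, _ = tune("lightgbm", X, y, space=point, n_trials=3, seed=0,
                       n_estimators=N_EST)
        assert best == {"num_leaves": 31, "learning_rate": 0.05}

    def test_search_space_ranges(self):
        """Every sampled trial stays inside the declared bounds."""
        X, y = _blobs(seed=5)
        _, trials = tune("xgboost", X, y, n_trials=15, seed=1,
                         n_estimators=N_EST)
        for t in trials:
            p = t["params"]
            assert 3 <= p["max_depth"] <= 10
            assert 1 <= p["min_child_weight"] <= 5
            assert 0.5 <= p["colsample_bytree"] <= 1.0
            assert 5e-3 <= p["learning_rate"] <= 0.1

    def test_beats_random_search_in_aggregate(self):
        """On harder (noisier) data, TPE's best trial should at least match
        a pure random search with the same budget, averaged over seeds."""
        diffs = []
        for seed in range(5):
            X, y = _blobs(n=200, d=20, informative=2, sep=1.0, seed=seed)
            best, trials = tune("lightgbm", X, y, n_trials=15, seed=seed,
                                n_estimators=N_EST)
            tpe_best = max(t["f1_macro"] for t in trials)
            # independent random-search baseline on the same budget
            rng = np.random.default_rng(10_000 + seed)
            space = SEARCH_SPACES["lightgbm"]
            X_fit, X_val, y_fit, y_val = train_test_split(
                X, y, test_size=0.1, stratify=y, random_state=seed)
            rand_best = -np.inf
            for _ in range(15):
                params = {p.name: p.sample(rng) for p in space.params}
                m = make_model("lightgbm", params, seed=seed,
                               n_estimators=N_EST)
                fit_model("lightgbm", m, X_fit, y_fit, X_val, y_val)
                cm = confusion_counts(y_val, m.predict(X_val),
                                      classes=np.unique(y))
                rand_best = max(rand_best, f1_macro(cm))
            diffs.append(tpe_best - rand_best)
        assert np.mean(diffs) >= -0.01

    def test_empty_and_single_class_rejected(self):
        with pytest.raises(ValueError):
            tune("lightgbm", np.empty((0, 3)), np.array([]), n_trials=1)
        with pytest.raises(ValueError):
            tune("lightgbm", np.zeros((10, 3)), np.array(["HC"] * 10),
                 n_trials=1)


@pytest.fixture(scope="module")
def separable():
    return _blobs(n=300, d=6, informative=1, sep=6.0, seed=7)


@pytest.fixture(scope="module")
def fitted(separable):
    X, y = separable
    return fit_stack(X, y, seed=0, n_estimators=N_EST, n_oof_folds=3)


class TestStackedEnsemble:
    def test_training_labels_recovered_on_separable_data(self, fitted,
                                                         separable):
        X, y = separable
        assert (fitted.predict(X) == y).mean() == 1.0

    def test_probabilities_sum_to_one(self, fitted, separable):
        X, _ = separable
        probs = fitted.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0

    def test_weights_convex(self, fitted):
        w = np.array(list(fitted.weights.values()))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)

    def test_degenerate_weights_equal_single_model(self, fitted, separable):
        X, _ = separable
        fitted_copy = fit_stack(*separable, seed=0, n_estimators=N_EST,
                                n_oof_folds=3)
        fitted_copy.weights = {"lightgbm": 1.0, "xgboost": 0.0, "gboost": 0.0}
        X2 = fitted_copy._layer2_input(X)
        expected = fitted_copy.layer2_models["lightgbm"].predict_proba(X2)
        assert np.allclose(fitted_copy.predict_proba(X), expected, atol=1e-12)

    def test_feature_width_checked(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict(np.zeros((3, 99)))

    def test_determinism(self, separable):
        X, y = separable
        a = fit_stack(X, y, seed=5, n_estimators=N_EST, n_oof_folds=3)
        b = fit_stack(X, y, seed=5, n_estimators=N_EST, n_oof_folds=3)
        assert a.weights == b.weights
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_stack(np.zeros((20, 3)), np.array(["HC"] * 20))

    def test_out_of_fold_discipline(self, monkeypatch, separable):
        """Layer-2 training rows must receive layer-1 probabilities from a
        model that did not train on that row: the OOF matrix differs from
        in-fold (refit) predictions on the training data."""
        from plistack import models as M

        X, y = separable
        captured = {}
        orig = M._oof_probabilities

        def spy(name, params, Xf, yf, classes, seed, n_folds, n_estimators):
            oof = orig(name, params, Xf, yf, classes, seed, n_folds,
                       n_estimators)
            if name == "lightgbm":
                model = M.make_model(name, params, seed=seed,
                                     n_estimators=n_estimators)
                M.fit_model(name, model, Xf, yf)
                captured["oof"] = oof
                captured["infold"] = M._predict_proba_full(model, Xf, classes)
            return oof

        monkeypatch.setattr(M, "_oof_probabilities", spy)
        M.fit_stack(X, y, seed=1, n_estimators=N_EST, n_oof_folds=3)
        assert not np.allclose(captured["oof"], captured["infold"])


def test_save_load_roundtrip_preserves_predictions(fitted, separable,
                                                   tmp_path):
    """Native-format persistence: a reloaded ensemble reproduces the
    original class probabilities exactly."""
    X, _ = separable
    fitted.save(tmp_path / "ens")
    from plistack.models import StackedEnsemble

    again = StackedEnsemble.load(tmp_path / "ens")
    assert list(again.classes_) == list(fitted.classes_)
    assert again.weights == fitted.weights
    np.testing.assert_allclose(again.predict_proba(X),
                               fitted.predict_proba(X), atol=1e-9)
    assert (again.predict(X) == fitted.predict(X)).all()
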