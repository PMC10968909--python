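"""Gradient-boosted base learners, Bayesian hyperparameter search and the
stacked ensemble with raw-feature passthrough.

Three gradient-boosting families serve as base learners: LightGBM, XGBoost
and sklearn's GradientBoostingClassifier (registry name "gboost").  Each
has a bounded hyperparameter search space (leaf/depth complexity, leaf
regularization, feature subsampling, log-uniform learning rate) explored
by a seedable tree-structured-Parzen-style sequential optimizer that
maximizes F1-macro on a held-out 10% validation split, 30 trials by
default.

The stacked ensemble is two layers deep: layer-1 base models produce
out-of-fold class probabilities on the training portion; layer-2 models of
the same three families train on the raw features concatenated with those
probabilities; a greedy forward ensemble selection (with replacement) over
the layer-2 models yields convex aggregation weights maximizing
validation F1-macro.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

MODEL_NAMES: tuple[str, ...] = ("lightgbm", "xgboost", "gboost")


def _validation_size(n: int, n_classes: int) -> int:
    """10% of the training portion, but at least one sample per class."""
    return max(n_classes, int(round(n * VALIDATION_FRACTION)))


def cv_splits(X, y, k: int, seed: int, groups=None):
    """Evaluation folds: stratified window-level k-fold by default, or
    subject-grouped k-fold (no subject in both train and test) when
    ``groups`` carries per-window subject ids — the leakage-safe mode."""
    from sklearn.model_selection import GroupKFold, StratifiedKFold

    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed % (2**31))
        return splitter.split(X, y)
    splitter = GroupKFold(n_splits=k, shuffle=True,
                          random_state=seed % (2**31))
    return splitter.split(X, y, groups=np.asarray(groups))

DEFAULT_N_TRIALS = 30
DEFAULT_N_ESTIMATORS = 300
EARLY_STOPPING_ROUNDS = 50
DEFAULT_OOF_FOLDS = 5
VALIDATION_FRACTION = 0.10


# ---------------------------------------------------------------------------
# search spaces


@dataclass(frozen=True)
class ParamSpec:
    name: str
    kind: str  # "int" | "uniform" | "loguniform"
    low: float
    high: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.low == self.high:
            x = self.low
        elif self.kind == "int":
            x = rng.integers(int(self.low), int(self.high) + 1)
        elif self.kind == "uniform":
            x = rng.uniform(self.low, self.high)
        elif self.kind == "loguniform":
            x = np.exp(rng.uniform(np.log(self.low), np.log(self.high)))
        else:
            raise ValueError(self.kind)
        return self.finalize(x)

    def finalize(self, x: float) -> float:
        x = min(max(float(x), self.low), self.high)
        return int(round(x)) if self.kind == "int" else x

    def to_internal(self, x: float) -> float:
        return float(np.log(x)) if self.kind == "loguniform" else float(x)

    def from_internal(self, u: float) -> float:
        x = float(np.exp(u)) if self.kind == "loguniform" else float(u)
        return self.finalize(x)


@dataclass(frozen=True)
class SearchSpace:
    model: str
    params: tuple[ParamSpec, ...]


#: Hyperparameter search spaces per base-learner family.
SEARCH_SPACES: dict[str, SearchSpace] = {
    "lightgbm": SearchSpace("lightgbm", (
        ParamSpec("num_leaves", "int", 16, 96),
        ParamSpec("min_data_in_leaf", "int", 2, 60),
        ParamSpec("feature_fraction", "uniform", 0.75, 1.0),
        ParamSpec("learning_rate", "loguniform", 5e-3, 0.1),
    )),
    "xgboost": SearchSpace("xgboost", (
        ParamSpec("max_depth", "int", 3, 10),
        ParamSpec("min_child_weight", "int", 1, 5),
        ParamSpec("colsample_bytree", "uniform", 0.5, 1.0),
        ParamSpec("learning_rate", "loguniform", 5e-3, 0.1),
    )),
    "gboost": SearchSpace("gboost", (
        ParamSpec("max_depth", "int", 5, 8),
        ParamSpec("min_samples_leaf", "int", 1, 5),
        ParamSpec("learning_rate", "loguniform", 5e-3, 0.1),
    )),
}


# ---------------------------------------------------------------------------
# base-learner construction / fitting


def make_model(name: str, params: Mapping[str, float] | None = None,
               seed: int = 0, n_estimators: int = DEFAULT_N_ESTIMATORS):
    """Instantiate one base learner with the given hyperparameters.

    Single-threaded and fully seeded so runs are reproducible.
    """
    params = dict(params or {})
    if name == "lightgbm":
        import lightgbm as lgb

        translated = {
            "num_leaves": int(params.get("num_leaves", 31)),
            "min_child_samples": int(params.get("min_data_in_leaf", 20)),
            "colsample_bytree": float(params.get("feature_fraction", 1.0)),
            "learning_rate": float(params.get("learning_rate", 0.1)),
        }
        return lgb.LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            deterministic=True, force_row_wise=True, verbose=-1, **translated,
        )
    if name == "xgboost":
        import xgboost as xgb

        return xgb.XGBClassifier(
            n_estimators=n_estimators,
            max_depth=int(params.get("max_depth", 6)),
            min_child_weight=float(params.get("min_child_weight", 1)),
            colsample_bytree=float(params.get("colsample_bytree", 1.0)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            random_state=seed, n_jobs=1, tree_method="hist",
            eval_metric="mlogloss", verbosity=0,
        )
    if name == "gboost":
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=int(params.get("max_depth", 3)),
            min_samples_leaf=int(params.get("min_samples_leaf", 1)),
            learning_rate=float(params.get("learning_rate", 0.1)),
            max_features="sqrt", random_state=seed,
            validation_fraction=VALIDATION_FRACTION,
        )
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def fit_model(name: str, model, X: np.ndarray, y: np.ndarray,
              X_val: np.ndarray | None = None,
              y_val: np.ndarray | None = None):
    """Fit one base learner, with early stopping on the validation split
    where the library supports an explicit evaluation set."""
    if name == "lightgbm" and X_val is not None:
        import lightgbm as lgb

        model.fit(X, y, eval_set=[(X_val, y_val)],
                  callbacks=[lgb.early_stopping(EARLY_STOPPING_ROUNDS,
                                                verbose=False)])
    elif name == "xgboost" and X_val is not None:
        model.set_params(early_stopping_rounds=EARLY_STOPPING_ROUNDS)
        model.fit(X, y, eval_set=[(X_val, y_val)], verbose=False)
    else:
        # gboost early-stops on its internal validation fraction, provided
        # the training portion is large enough to carve one off
        if name == "gboost":
            n_classes = len(np.unique(y))
            if int(len(X) * VALIDATION_FRACTION) > n_classes:
                model.set_params(n_iter_no_change=10)
        model.fit(X, y)
    return model


def feature_importances(name: str, model) -> np.ndarray:
    """Native gain-style feature importances, normalized to sum to 1."""
    if name == "lightgbm":
        imp = model.booster_.feature_importance(importance_type="gain")
    elif name == "xgboost":
        booster = model.get_booster()
        scores = booster.get_score(importance_type="total_gain")
        imp = np.zeros(model.n_features_in_)
        for key, val in scores.items():
            imp[int(key[1:])] = val
    else:
        imp = model.feature_importances_
    imp = np.asarray(imp, dtype=np.float64)
    total = imp.sum()
    return imp / total if total > 0 else imp


def importance_ranking(imp: np.ndarray) -> np.ndarray:
    """Descending-importance permutation; ties broken by ascending id."""
    d = len(imp)
    return np.lexsort((np.arange(d), -imp))


# ---------------------------------------------------------------------------
# TPE-style sequential hyperparameter optimization


class TPESampler:
    """Tree-structured-Parzen-style sequential sampler.

    The first ``n_startup`` trials are uniform random; afterwards observed
    trials are split into the best quantile ("good") and the rest, one
    Gaussian KDE per dimension is fitted to each side (in internal
    coordinates: log scale for log-uniform parameters), and candidates
    drawn from the good density are scored by the density ratio
    good/bad, keeping the best candidate.
    """

    def __init__(self, space: SearchSpace, seed: int = 0,
                 n_startup: int = 10, gamma: float = 0.25,
                 n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.history: list[tuple[dict[str, float], float]] = []

    def _random_params(self) -> dict[str, float]:
        return {p.name: p.sample(self.rng) for p in self.space.params}

    def suggest(self) -> dict[str, float]:
        if len(self.history) < self.n_startup:
            return self._random_params()
        scores = np.array([s for _, s in self.history])
        n_good = max(2, int(round(self.gamma * len(scores))))
        order = np.argsort(-scores)
        good_idx, bad_idx = order[:n_good], order[n_good:]
        if len(bad_idx) < 2:
            return self._random_params()

        params_out: dict[str, float] = {}
        cand = {}
        log_ratio = np.zeros(self.n_candidates)
        for p in self.space.params:
            vals = np.array([self.to_float(h[0][p.name], p) for h in self.history])
            good, bad = vals[good_idx], vals[bad_idx]
            if p.low == p.high or np.ptp(good) == 0 or np.ptp(bad) == 0:
                cand[p.name] = np.full(self.n_candidates,
                                       p.to_internal(p.finalize(good[0]))
                                       if p.low != p.high else p.to_internal(p.low))
                continue
            kde_good = gaussian_kde(good)
            kde_bad = gaussian_kde(bad)
            draw_seed = int(self.rng.integers(0, 2**31 - 1))
            draws = kde_good.resample(self.n_candidates, seed=draw_seed)[0]
            lo, hi = p.to_internal(p.low), p.to_internal(p.high)
            draws = np.clip(draws, lo, hi)
            with np.errstate(divide="ignore"):
                log_ratio += np.log(kde_good(draws) + 1e-300) - np.log(
                    kde_bad(draws) + 1e-300)
            cand[p.name] = draws
        best = int(np.argmax(log_ratio))
        for p in self.space.params:
            params_out[p.name] = p.from_internal(float(cand[p.name][best]))
        return params_out

    @staticmethod
    def to_float(value: float, spec: ParamSpec) -> float:
        return spec.to_internal(float(value))

    def tell(self, params: dict[str, float], score: float) -> None:
        self.history.append((dict(params), float(score)))


def tune(model_name: str, X: np.ndarray, y: np.ndarray,
         space: SearchSpace | None = None, n_trials: int = DEFAULT_N_TRIALS,
         seed: int = 0, n_estimators: int = DEFAULT_N_ESTIMATORS,
         ) -> tuple[dict[str, float], list[dict]]:
    """Sequential model-based hyperparameter search maximizing F1-macro on
    a stratified 10% validation split.  Returns (best params, trial log)."""
    from .metrics import confusion_counts, f1_macro

    if len(X) == 0:
        raise ValueError("empty training data")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to tune")
    space = space or SEARCH_SPACES[model_name]
    classes, y_enc = encode_labels(y)
    X_fit, X_val, y_fit, y_val = train_test_split(
        X, y_enc, test_size=_validation_size(len(X), len(classes)),
        stratify=y_enc, random_state=seed)
    sampler = TPESampler(space, seed=seed)
    trials = []
    best_params, best_score = None, -np.inf
    for t in range(n_trials):
        params = sampler.suggest()
        model = make_model(model_name, params, seed=seed,
                           n_estimators=n_estimators)
        fit_model(model_name, model, X_fit, y_fit, X_val, y_val)
        cm = confusion_counts(y_val, model.predict(X_val),
                              classes=np.arange(len(classes)))
        score = f1_macro(cm)
        sampler.tell(params, score)
        trials.append({"trial": t, "params": dict(params), "f1_macro": score})
        if score > best_score:
            best_params, best_score = dict(params), score
    return best_params, trials


# ---------------------------------------------------------------------------
# stacked ensemble


@dataclass
class StackedEnsemble:
    """Two-layer stack with raw-feature passthrough and convex
    ensemble-selection weights over the layer-2 models."""

    classes_: np.ndarray
    base_models: dict[str, object]
    layer2_models: dict[str, object]
    weights: dict[str, float]
    n_features_in_: int

    def _layer2_input(self, X: np.ndarray) -> np.ndarray:
        base_probs = [
            _predict_proba_full(self.base_models[m], X, self.classes_)
            for m in MODEL_NAMES
        ]
        return np.hstack([X] + base_probs)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} != training width "
                f"{self.n_features_in_}")
        X2 = self._layer2_input(X)
        agg = np.zeros((X.shape[0], len(self.classes_)))
        for m, w in self.weights.items():
            if w > 0:
                agg += w * _predict_proba_full(self.layer2_models[m], X2,
                                               self.classes_)
        return agg / agg.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def save(self, directory) -> None:
        """Persist the ensemble: each model in its library's native format
        (LightGBM booster text, XGBoost JSON, joblib for sklearn) plus a
        JSON manifest with classes, weights and feature width."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for layer, models in (("base", self.base_models),
                              ("layer2", self.layer2_models)):
            for name, model in models.items():
                _save_native(name, model, directory / f"{layer}_{name}")
        manifest = {
            "classes": [str(c) for c in self.classes_],
            "weights": self.weights,
            "n_features_in": int(self.n_features_in_),
        }
        import json

        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "StackedEnsemble":
        import json
        from pathlib import Path

        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        base = {name: _load_native(name, directory / f"base_{name}")
                for name in MODEL_NAMES}
        layer2 = {name: _load_native(name, directory / f"layer2_{name}")
                  for name in MODEL_NAMES}
        return cls(
            classes_=np.array(manifest["classes"]),
            base_models=base, layer2_models=layer2,
            weights={m: float(w) for m, w in manifest["weights"].items()},
            n_features_in_=int(manifest["n_features_in"]),
        )


class _LGBMBoosterShim:
    """predict_proba/classes_ facade over a bare LightGBM booster loaded
    from its native text format."""

    def __init__(self, booster):
        self.booster = booster
        self.classes_ = np.arange(booster.num_model_per_iteration())

    def predict_proba(self, X):
        probs = self.booster.predict(X)
        return np.atleast_2d(probs)


class _XGBBoosterShim:
    """predict_proba/classes_ facade over a bare XGBoost booster loaded
    from its native JSON format."""

    def __init__(self, booster):
        self.booster = booster
        import json

        cfg = json.loads(booster.save_config())
        n_classes = int(cfg["learner"]["learner_model_param"]["num_class"] or 2)
        self.classes_ = np.arange(max(n_classes, 2))

    def predict_proba(self, X):
        import xgboost as xgb

        probs = self.booster.predict(xgb.DMatrix(np.asarray(X)))
        return np.atleast_2d(probs)


def _save_native(name: str, model, stem) -> None:
    if name == "lightgbm":
        model.booster_.save_model(str(stem) + ".txt")
    elif name == "xgboost":
        model.get_booster().save_model(str(stem) + ".json")
    else:
        import joblib

        joblib.dump(model, str(stem) + ".joblib")


def _load_native(name: str, stem):
    if name == "lightgbm":
        import lightgbm as lgb

        return _LGBMBoosterShim(lgb.Booster(model_file=str(stem) + ".txt"))
    if name == "xgboost":
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(str(stem) + ".json")
        return _XGBBoosterShim(booster)
    import joblib

    return joblib.load(str(stem) + ".joblib")


def encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sorted class labels, integer-encoded y) — boosted-tree libraries
    require contiguous integer classes."""
    classes, y_enc = np.unique(np.asarray(y), return_inverse=True)
    return classes, y_enc


def _encode(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y])


def _predict_proba_full(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Class probabilities aligned to the full class list (classes absent
    from a fold's training data get probability zero)."""
    probs = model.predict_proba(X)
    seen = np.asarray(model.classes_)
    out = np.zeros((X.shape[0], len(classes)))
    out[:, seen.astype(int)] = probs
    return out


def _oof_probabilities(name: str, params: Mapping[str, float], X, y_enc,
                       classes, seed: int, n_folds: int,
                       n_estimators: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros((len(X), len(classes)))
    for fold, (tr, te) in enumerate(skf.split(X, y_enc)):
        model = make_model(name, params, seed=seed + fold,
                           n_estimators=n_estimators)
        fit_model(name, model, X[tr], y_enc[tr])
        oof[te] = _predict_proba_full(model, X[te], classes)
    return oof


def greedy_ensemble_weights(
    model_probs: Mapping[str, np.ndarray], y_true_enc: np.ndarray,
    classes: np.ndarray, n_rounds: int = 15,
) -> dict[str, float]:
    """Caruana-style forward selection with replacement: each round adds
    the model whose inclusion maximizes validation F1-macro of the
    averaged probabilities.  Returns convex weights."""
    from .metrics import confusion_counts, f1_macro

    names = list(model_probs)
    counts = {m: 0 for m in names}
    agg = np.zeros_like(next(iter(model_probs.values())))
    total = 0
    for _ in range(n_rounds):
        best_m, best_score = None, -np.inf
        for m in names:
            trial = (agg + model_probs[m]) / (total + 1)
            pred = np.argmax(trial, axis=1)
            cm = confusion_counts(y_true_enc, pred,
                                  classes=np.arange(len(classes)))
            score = f1_macro(cm)
            if score > best_score:
                best_m, best_score = m, score
        counts[best_m] += 1
        agg += model_probs[best_m]
        total += 1
    return {m: counts[m] / total for m in names}


def fit_stack(X: np.ndarray, y: np.ndarray,
              params_per_model: Mapping[str, Mapping[str, float]] | None = None,
              seed: int = 0, n_estimators: int = DEFAULT_N_ESTIMATORS,
              n_oof_folds: int = DEFAULT_OOF_FOLDS) -> StackedEnsemble:
    """Fit the two-layer stacked ensemble.

    A stratified 10% validation split is carved off first; it drives
    base-model early stopping and the greedy ensemble selection.  Layer-2
    models are trained only on out-of-fold layer-1 probabilities, so they
    never see base-model predictions on data those bases were fit on.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    params_per_model = params_per_model or {m: {} for m in MODEL_NAMES}
    y_enc = _encode(y, classes)

    X_fit, X_val, y_fit, y_val = train_test_split(
        X, y_enc, test_size=_validation_size(len(X), len(classes)),
        stratify=y_enc, random_state=seed)

    base_models: dict[str, object] = {}
    oof_blocks = []
    val_blocks = []
    for name in MODEL_NAMES:
        params = params_per_model.get(name, {})
        oof_blocks.append(_oof_probabilities(
            name, params, X_fit, y_fit, classes, seed=seed,
            n_folds=n_oof_folds, n_estimators=n_estimators))
        model = make_model(name, params, seed=seed, n_estimators=n_estimators)
        fit_model(name, model, X_fit, y_fit, X_val, y_val)
        base_models[name] = model
        val_blocks.append(_predict_proba_full(model, X_val, classes))

    X2_fit = np.hstack([X_fit] + oof_blocks)
    X2_val = np.hstack([X_val] + val_blocks)

    layer2_models: dict[str, object] = {}
    val_probs: dict[str, np.ndarray] = {}
    for name in MODEL_NAMES:
        params = params_per_model.get(name, {})
        model = make_model(name, params, seed=seed + 1000,
                           n_estimators=n_estimators)
        fit_model(name, model, X2_fit, y_fit, X2_val, y_val)
        layer2_models[name] = model
        val_probs[name] = _predict_proba_full(model, X2_val, classes)

    weights = greedy_ensemble_weights(val_probs, y_val, classes)
    return StackedEnsemble(
        classes_=classes, base_models=base_models,
        layer2_models=layer2_models, weights=weights,
        n_features_in_=X.shape[1],
    )
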