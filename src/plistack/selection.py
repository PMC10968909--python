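"""Multi-model joint feature selection.

Stage 1 — feature ranking: for each base-learner family, repeated
stratified k-fold training (p repeats × k folds, 10% of each training
portion held out as validation for early stopping) produces one
descending-importance permutation of all features per (repeat, fold),
from the model's native gain importances.  The three per-model ranking
matrices are concatenated row-wise into the importance index of shape
(3·p·k) × d.  Study-scale defaults are p = 100, k = 5.

Stage 2 — subset selection: for a candidate size n, each feature is
scored by how often it appears within the first n columns across all
index rows; the n most frequent features form the candidate subset.
Candidate subsets are evaluated with the stacked ensemble under repeated
stratified k-fold (p_eval = 5, k_eval = 5 by default) and the subset with
the highest mean ensemble accuracy wins (ties go to the smaller n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import confusion_counts, metrics_report
from .models import (
    DEFAULT_N_ESTIMATORS,
    _validation_size,
    cv_splits,
    MODEL_NAMES,
    feature_importances,
    fit_model,
    fit_stack,
    importance_ranking,
    make_model,
)

DEFAULT_P_RANK = 100
DEFAULT_K_RANK = 5
DEFAULT_P_EVAL = 5
DEFAULT_K_EVAL = 5


@dataclass
class ImportanceIndex:
    """Concatenated descending-importance ranking matrix.

    ``rows[r]`` is a permutation of {0..d-1}; ``provenance[r]`` records
    (model name, repeat, fold) for that row.
    """

    rows: np.ndarray
    provenance: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.ndim != 2 or self.rows.shape[0] == 0:
            raise ValueError("index must be a non-empty 2-D matrix")
        if len(self.provenance) != self.rows.shape[0]:
            raise ValueError("provenance length mismatch")
        d = self.rows.shape[1]
        ref = np.arange(d)
        for r, row in enumerate(self.rows):
            if not np.array_equal(np.sort(row), ref):
                raise ValueError(f"index row {r} is not a permutation of 0..{d-1}")

    @property
    def d_feature(self) -> int:
        return self.rows.shape[1]


def rank_features(X: np.ndarray, y: np.ndarray, model_name: str,
                  p: int = DEFAULT_P_RANK, k: int = DEFAULT_K_RANK,
                  seed: int = 0,
                  n_estimators: int = DEFAULT_N_ESTIMATORS) -> ImportanceIndex:
    """Per-model importance ranking over p repeats of stratified k-fold.

    Emits p·k rows, each the descending-importance permutation from one
    (repeat, fold) training run; ties break by ascending feature id.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    X = np.asarray(X, dtype=np.float64)
    from .models import encode_labels

    _, y = encode_labels(y)
    if len(X) < k:
        raise ValueError("fewer samples than folds")
    rows = []
    provenance = []
    for r in range(p):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed + 7919 * r) % (2**31))
        for f, (train_idx, _test_idx) in enumerate(skf.split(X, y)):
            X_tr, y_tr = X[train_idx], y[train_idx]
            n_classes = len(np.unique(y_tr))
            X_fit, X_val, y_fit, y_val = train_test_split(
                X_tr, y_tr,
                test_size=_validation_size(len(X_tr), n_classes),
                stratify=y_tr,
                random_state=(seed + 104729 * r + f) % (2**31))
            model = make_model(model_name, seed=seed + r,
                               n_estimators=n_estimators)
            fit_model(model_name, model, X_fit, y_fit, X_val, y_val)
            imp = feature_importances(model_name, model)
            rows.append(importance_ranking(imp))
            provenance.append((model_name, r, f))
    return ImportanceIndex(np.array(rows), provenance)


def build_index(i_lightgbm: ImportanceIndex, i_gboost: ImportanceIndex,
                i_xgboost: ImportanceIndex) -> ImportanceIndex:
    """Row-wise concatenation of the three per-model ranking matrices,
    in the fixed model order (LightGBM, third family, XGBoost)."""
    parts = (i_lightgbm, i_gboost, i_xgboost)
    widths = {p.d_feature for p in parts}
    if len(widths) != 1:
        raise ValueError(f"feature-count mismatch across sub-indices: {widths}")
    rows = np.vstack([p.rows for p in parts])
    provenance = sum((p.provenance for p in parts), [])
    return ImportanceIndex(rows, provenance)


def build_full_index(X: np.ndarray, y: np.ndarray,
                     p: int = DEFAULT_P_RANK, k: int = DEFAULT_K_RANK,
                     seed: int = 0,
                     n_estimators: int = DEFAULT_N_ESTIMATORS
                     ) -> ImportanceIndex:
    """Rank with all three families and concatenate (shape (3·p·k) × d)."""
    return build_index(
        rank_features(X, y, "lightgbm", p, k, seed, n_estimators),
        rank_features(X, y, "gboost", p, k, seed, n_estimators),
        rank_features(X, y, "xgboost", p, k, seed, n_estimators),
    )


def frequency_subset(index: ImportanceIndex, n: int) -> np.ndarray:
    """The n features appearing most frequently within the first n columns
    of the index rows.

    Ties break by better (smaller) mean rank position across all rows,
    then by ascending feature id.  Returns a sorted array of feature ids.
    """
    d = index.d_feature
    if not 1 <= n <= d:
        raise ValueError(f"subset size {n} out of range [1, {d}]")
    top = index.rows[:, :n]
    counts = np.bincount(top.ravel(), minlength=d)
    # mean rank position of each feature over all rows
    positions = np.empty_like(index.rows)
    np.put_along_axis(positions, index.rows,
                      np.broadcast_to(np.arange(d), index.rows.shape), axis=1)
    mean_pos = positions.mean(axis=0)
    order = sorted(range(d), key=lambda j: (-counts[j], mean_pos[j], j))
    return np.sort(np.array(order[:n], dtype=np.int64))


@dataclass
class SubsetEvaluation:
    """Evaluation of one candidate feature subset under the ensemble."""

    n: int
    features: np.ndarray
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.features) != self.n:
            raise ValueError("subset size mismatch")


def evaluate_subset(X: np.ndarray, y: np.ndarray, features: np.ndarray,
                    params_per_model: Mapping | None = None,
                    p_eval: int = DEFAULT_P_EVAL, k_eval: int = DEFAULT_K_EVAL,
                    seed: int = 0,
                    n_estimators: int = DEFAULT_N_ESTIMATORS,
                    n_oof_folds: int = 5, groups=None) -> SubsetEvaluation:
    """Repeated stratified k-fold evaluation of the stacked ensemble on a
    feature subset; reports mean ± sd of the four headline metrics.

    Pass per-window subject ids as ``groups`` for the subject-grouped
    (leakage-safe) fold mode."""
    X = np.asarray(X, dtype=np.float64)[:, features]
    y = np.asarray(y)
    per_fold = {m: [] for m in ("accuracy", "f1_macro", "gmean_macro", "kappa")}
    for r in range(p_eval):
        folds = cv_splits(X, y, k_eval, seed + 15485863 * r, groups)
        for f, (tr, te) in enumerate(folds):
            ens = fit_stack(X[tr], y[tr], params_per_model,
                            seed=(seed + 31 * r + f) % (2**31),
                            n_estimators=n_estimators,
                            n_oof_folds=n_oof_folds)
            cm = confusion_counts(y[te], ens.predict(X[te]),
                                  classes=np.unique(y))
            for key, val in metrics_report(cm).items():
                per_fold[key].append(val)
    return SubsetEvaluation(
        n=len(features), features=np.asarray(features),
        metrics_mean={m: float(np.mean(v)) for m, v in per_fold.items()},
        metrics_sd={m: float(np.std(v, ddof=1)) for m, v in per_fold.items()},
    )


def select_optimal_subset(
    index: ImportanceIndex, X: np.ndarray, y: np.ndarray,
    candidate_sizes: Sequence[int] | None = None,
    params_per_model: Mapping | None = None,
    p_eval: int = DEFAULT_P_EVAL, k_eval: int = DEFAULT_K_EVAL,
    seed: int = 0, n_estimators: int = DEFAULT_N_ESTIMATORS,
    n_oof_folds: int = 5, stride: int = 1, criterion: str = "accuracy",
    groups=None,
) -> tuple[SubsetEvaluation, pd.DataFrame]:
    """Sweep candidate subset sizes and return (best subset, full sweep).

    ``candidate_sizes`` defaults to every n in [1, d] with the given
    stride.  Best = highest mean ensemble ``criterion`` (accuracy by
    default); ties go to the smallest n.
    """
    d = index.d_feature
    if candidate_sizes is None:
        candidate_sizes = list(range(stride, d + 1, stride))
    if any(not 1 <= n <= d for n in candidate_sizes):
        raise ValueError("candidate sizes must lie in [1, d_feature]")

    evaluations: list[SubsetEvaluation] = []
    rows = []
    for n in sorted(candidate_sizes):
        subset = frequency_subset(index, n)
        ev = evaluate_subset(X, y, subset, params_per_model, p_eval, k_eval,
                             seed, n_estimators, n_oof_folds, groups=groups)
        evaluations.append(ev)
        row = {"n": n}
        for m in ev.metrics_mean:
            row[m] = ev.metrics_mean[m]
            row[f"{m}_sd"] = ev.metrics_sd[m]
        rows.append(row)
    sweep = pd.DataFrame(rows)
    best = max(evaluations, key=lambda ev: (ev.metrics_mean[criterion], -ev.n))
    return best, sweep
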