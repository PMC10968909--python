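"""Experiment drivers: four-model evaluation, the time-window sweep and
the per-rhythm classification comparison."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import feature_table, split_feature_table
from .metrics import confusion_counts, metrics_report
from .models import (
    DEFAULT_N_ESTIMATORS,
    MODEL_NAMES,
    cv_splits,
    encode_labels,
    fit_model,
    fit_stack,
    make_model,
)
from .montage import BAND_NAMES
from .preprocess import preprocess_recording
from .recording import EEGRecording
from .report import decode_feature

ALL_MODELS: tuple[str, ...] = MODEL_NAMES + ("ensemble",)


def evaluate_models(
    X: np.ndarray, y: np.ndarray,
    params_per_model: Mapping | None = None,
    p_eval: int = 5, k_eval: int = 5, seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS, n_oof_folds: int = 5,
    groups=None,
) -> tuple[pd.DataFrame, dict[str, dict[str, list[float]]]]:
    """Repeated stratified k-fold evaluation of the three base learners
    and the stacked ensemble.

    Returns a summary table (model, metric mean ± sd) and the raw
    per-fold metric samples (for the cross-model statistical comparison).
    Pass per-window subject ids as ``groups`` for subject-grouped
    (leakage-safe) folds instead of window-level stratified ones.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, y_enc = encode_labels(y)
    params_per_model = params_per_model or {m: {} for m in MODEL_NAMES}
    samples: dict[str, dict[str, list[float]]] = {
        m: {k: [] for k in ("accuracy", "f1_macro", "gmean_macro", "kappa")}
        for m in ALL_MODELS
    }
    for r in range(p_eval):
        folds = cv_splits(X, y, k_eval, seed + 60013 * r, groups)
        for f, (tr, te) in enumerate(folds):
            fold_seed = (seed + 31 * r + f) % (2**31)
            for name in MODEL_NAMES:
                model = make_model(name, params_per_model.get(name, {}),
                                   seed=fold_seed, n_estimators=n_estimators)
                fit_model(name, model, X[tr], y_enc[tr])
                cm = confusion_counts(y[te], classes[model.predict(X[te])],
                                      classes)
                for key, val in metrics_report(cm).items():
                    samples[name][key].append(val)
            ens = fit_stack(X[tr], y[tr], params_per_model, seed=fold_seed,
                            n_estimators=n_estimators, n_oof_folds=n_oof_folds)
            cm = confusion_counts(y[te], ens.predict(X[te]), classes)
            for key, val in metrics_report(cm).items():
                samples["ensemble"][key].append(val)

    rows = []
    for m in ALL_MODELS:
        row: dict[str, object] = {"model": m}
        for key, vals in samples[m].items():
            row[key] = float(np.mean(vals))
            row[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows), samples


def cohort_features(recordings: Sequence[EEGRecording], window_length: float
                    ) -> pd.DataFrame:
    """Preprocess a cohort and assemble the per-window PLI feature table."""
    all_windows = []
    for rec in recordings:
        all_windows.extend(preprocess_recording(rec, window_length))
    return feature_table(all_windows)


def window_sweep(
    recordings: Sequence[EEGRecording],
    window_lengths: Sequence[float] = (2, 4, 6, 8, 10, 12, 14, 16),
    params_per_model: Mapping | None = None,
    p_eval: int = 5, k_eval: int = 5, seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS, n_oof_folds: int = 5,
) -> pd.DataFrame:
    """Full pipeline per window length, four models each.

    Returns one row per (window_length, model) with metric means ± sd.
    """
    frames = []
    for wl in window_lengths:
        df = cohort_features(recordings, wl)
        X, y, _ = split_feature_table(df)
        summary, _ = evaluate_models(X, y, params_per_model, p_eval, k_eval,
                                     seed, n_estimators, n_oof_folds)
        summary.insert(0, "window_length", wl)
        frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def rhythm_experiments(
    selected_ids: Sequence[int], feature_df: pd.DataFrame,
    params_per_model: Mapping | None = None,
    p_eval: int = 5, k_eval: int = 5, seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS, n_oof_folds: int = 5,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Evaluate the selected key features per rhythm and combined.

    One experiment per rhythm slice of the selected subset plus the "all"
    slice; rhythms with no selected feature are skipped with a warning.
    Returns the summary table and per-slice raw metric samples.
    """
    X, y, _names = split_feature_table(feature_df)
    selected_ids = np.asarray(sorted(int(i) for i in selected_ids))
    slices: dict[str, np.ndarray] = {"all": selected_ids}
    for band in BAND_NAMES:
        ids = np.array([i for i in selected_ids
                        if decode_feature(int(i)).band == band], dtype=np.int64)
        slices[band] = ids

    frames = []
    all_samples: dict[str, dict] = {}
    for rhythm, ids in slices.items():
        if len(ids) == 0:
            warnings.warn(f"no selected features in rhythm {rhythm!r}; skipped",
                          UserWarning, stacklevel=2)
            continue
        summary, samples = evaluate_models(
            X[:, ids], y, params_per_model, p_eval, k_eval, seed,
            n_estimators, n_oof_folds)
        summary.insert(0, "rhythm", rhythm)
        summary.insert(1, "n_features", len(ids))
        frames.append(summary)
        all_samples[rhythm] = samples
    return pd.concat(frames, ignore_index=True), all_samples
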