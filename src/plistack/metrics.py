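"""Multiclass evaluation metrics and cross-model statistical comparison.

Metrics operate on a confusion-count matrix (rows = true class, columns =
predicted class, in a fixed class order):

* accuracy           — trace / total
* F1-macro           — unweighted mean of per-class F1 (0 where a class has
                       neither true nor predicted positives)
* Gmean-macro        — mean over classes of sqrt(precision_i · recall_i)
* kappa              — (Po − Pe)/(1 − Pe), with two Pe variants:
                       "cohen" (marginal-product expected agreement, the
                       standard definition) and "printed" (Pe = accuracy²,
                       a non-standard variant kept for comparability)

The model-comparison helper runs a one-way ANOVA across models' repeat-
level metric samples followed by Tukey-HSD post hoc contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .montage import GROUPS


def confusion_counts(y_true: Sequence, y_pred: Sequence,
                     classes: Sequence = GROUPS) -> np.ndarray:
    """Confusion-count matrix with rows=true, columns=predicted."""
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred, strict=True):
        cm[idx[t], idx[p]] += 1
    return cm


def _check(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    if (cm < 0).any():
        raise ValueError("negative counts")
    return cm


def accuracy(cm: np.ndarray) -> float:
    cm = _check(cm)
    return float(np.trace(cm) / cm.sum())


def _precision_recall(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(cm).astype(float)
    pred = cm.sum(axis=0).astype(float)
    true = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(true > 0, tp / true, 0.0)
    return precision, recall


def f1_macro(cm: np.ndarray) -> float:
    cm = _check(cm)
    precision, recall = _precision_recall(cm)
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1),
                  0.0)
    return float(f1.mean())


def gmean_macro(cm: np.ndarray) -> float:
    cm = _check(cm)
    precision, recall = _precision_recall(cm)
    return float(np.sqrt(precision * recall).mean())


def kappa(cm: np.ndarray, variant: str = "cohen") -> float:
    cm = _check(cm)
    po = accuracy(cm)
    if variant == "printed":
        pe = po**2
    elif variant == "cohen":
        total = cm.sum()
        pe = float((cm.sum(axis=0) * cm.sum(axis=1)).sum() / total**2)
    else:
        raise ValueError(f"unknown kappa variant {variant!r}")
    if pe == 1.0:
        raise ValueError("degenerate expected agreement Pe = 1")
    return float((po - pe) / (1.0 - pe))


def metrics_report(cm: np.ndarray, kappa_variant: str = "cohen"
                   ) -> dict[str, float]:
    """All four headline metrics for one confusion matrix."""
    return {
        "accuracy": accuracy(cm),
        "f1_macro": f1_macro(cm),
        "gmean_macro": gmean_macro(cm),
        "kappa": kappa(cm, kappa_variant),
    }


# ---------------------------------------------------------------------------
# cross-model statistical comparison


def significance_tier(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ModelComparison:
    omnibus_p: float
    omnibus_tier: str
    pairwise: pd.DataFrame  # columns: model, reference, p_adj, tier


def compare_models(samples: Mapping[str, Sequence[float]],
                   reference: str = "ensemble") -> ModelComparison:
    """One-way ANOVA across models' repeat-level metric samples, with
    Tukey-HSD contrasts of each sub-model against the reference model.
    """
    names = list(samples)
    arrays = [np.asarray(samples[m], dtype=float) for m in names]
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least two samples per model")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # identical constant samples: no evidence of any difference
        pairwise = pd.DataFrame(
            [(m, reference, 1.0, "") for m in names if m != reference],
            columns=["model", "reference", "p_adj", "tier"],
        )
        return ModelComparison(1.0, "", pairwise)

    _, p_omnibus = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    ref_idx = names.index(reference) if reference in names else 0
    rows = []
    for i, m in enumerate(names):
        if i == ref_idx:
            continue
        p_adj = float(res.pvalue[i, ref_idx])
        rows.append((m, names[ref_idx], p_adj, significance_tier(p_adj)))
    pairwise = pd.DataFrame(rows, columns=["model", "reference", "p_adj", "tier"])
    return ModelComparison(float(p_omnibus), significance_tier(float(p_omnibus)),
                           pairwise)
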