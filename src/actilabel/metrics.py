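"""Evaluation metrics for clustering quality and transferred labels.

Four metrics, with the exact conventions used throughout the package:

* ``nmi`` — normalised mutual information, ``2 I(L;C) / (H(L) + H(C))``,
  entropies in bits (the base cancels in the ratio); 1 when both label
  vectors are single-class (perfect, if vacuous, agreement).
* ``purity`` — each cluster votes its most frequent true label;
  sum of the majority counts over N.
* ``labeling_accuracy`` — macro (unweighted) one-vs-rest accuracy
  ``mean_k (TP_k + TN_k) / n`` over the classes present in the true vector.
* ``precision_recall_f1`` — macro precision and recall; F1 is by default
  the harmonic mean of the two macro averages ("printed" convention), with
  the macro-average of per-class F1 scores available via
  ``f1_mode="macro_f1"``.  A class never predicted contributes precision 0.

Plus a small harness around the default downstream classifier: 5-nearest
neighbours under cosine distance, the strongest of the simple feature-space
baselines for this kind of windowed inertial data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "nmi",
    "purity",
    "labeling_accuracy",
    "precision_recall_f1",
    "train_eval_classifier",
    "stratified_split",
    "evaluate_labels",
]

logger = logging.getLogger(__name__)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("label vectors must be non-empty")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(L, C) -> float:
    """Normalised mutual information between two labelings, in [0, 1]."""
    L, C = _check_pair(L, C)
    T = _contingency(L, C)
    n = T.sum()
    hl = _entropy_bits(T.sum(axis=1))
    hc = _entropy_bits(T.sum(axis=0))
    if hl + hc == 0:
        return 1.0  # both single-class
    pl = T.sum(axis=1) / n
    pc = T.sum(axis=0) / n
    pij = T / n
    outer = np.outer(pl, pc)
    mask = pij > 0
    mi = float((pij[mask] * np.log2(pij[mask] / outer[mask])).sum())
    return 2.0 * mi / (hl + hc)


def purity(C, L) -> float:
    """Fraction of observations covered by each cluster's majority label."""
    C, L = _check_pair(C, L)
    T = _contingency(C, L)
    return float(T.max(axis=1).sum() / T.sum())


def _binary_counts(true: np.ndarray, pred: np.ndarray, cls) -> tuple[int, int, int, int]:
    t = true == cls
    p = pred == cls
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    return tp, fp, fn, tn


def labeling_accuracy(true, assigned) -> float:
    """Macro one-vs-rest accuracy of transferred labels.

    Averaged over the classes present in ``true``; labels in ``assigned``
    outside that alphabet (e.g. fallback markers) only ever count against
    the per-class accuracies.
    """
    true, assigned = _check_pair(true, assigned)
    classes = sorted(pd.unique(true).tolist())
    n = true.size
    accs = []
    for cls in classes:
        tp, fp, fn, tn = _binary_counts(true, assigned, cls)
        accs.append((tp + tn) / n)
    return float(np.mean(accs))


def precision_recall_f1(true, pred, f1_mode: str = "printed") -> tuple[float, float, float]:
    """Macro precision, macro recall and F1.

    ``f1_mode="printed"`` (default): F1 = harmonic mean of the macro
    precision and macro recall.  ``f1_mode="macro_f1"``: mean of per-class
    F1 scores.  Classes are those present in ``true``; zero denominators
    contribute 0.
    """
    true, pred = _check_pair(true, pred)
    classes = sorted(pd.unique(true).tolist())
    precisions, recalls, f1s = [], [], []
    for cls in classes:
        tp, fp, fn, _ = _binary_counts(true, pred, cls)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    P = float(np.mean(precisions))
    R = float(np.mean(recalls))
    if f1_mode == "printed":
        F1 = 2 * P * R / (P + R) if P + R else 0.0
    elif f1_mode == "macro_f1":
        F1 = float(np.mean(f1s))
    else:
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    return P, R, float(F1)


def evaluate_labels(true, pred, f1_mode: str = "printed") -> dict:
    """All four metrics in one report (JSON-serialisable dict)."""
    P, R, F1 = precision_recall_f1(true, pred, f1_mode=f1_mode)
    return {
        "nmi": nmi(true, pred),
        "purity": purity(pred, true),
        "labeling_accuracy": labeling_accuracy(true, pred),
        "precision": P,
        "recall": R,
        "f1": F1,
    }


def stratified_split(
    n: int,
    labels,
    fractions: tuple[float, float, float] = (0.5, 0.25, 0.25),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class shuffled train/test/validation index split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for cls in sorted(pd.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        a = int(round(fractions[0] * len(idx)))
        b = a + int(round(fractions[1] * len(idx)))
        train.extend(idx[:a])
        test.extend(idx[a:b])
        val.extend(idx[b:])
    return (np.sort(train).astype(int), np.sort(test).astype(int),
            np.sort(val).astype(int))


def _make_classifier(spec: str | object = "5nn"):
    if not isinstance(spec, str):
        return spec  # already an estimator
    if spec.endswith("nn") and spec[:-2].isdigit():
        return KNeighborsClassifier(n_neighbors=int(spec[:-2]), metric="cosine")
    raise ValueError(f"unknown classifier spec {spec!r}")


@dataclass
class ClassifierReport:
    precision: float
    recall: float
    f1: float
    n_train: int
    n_test: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def train_eval_classifier(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    classifier_spec: str | object = "5nn",
    f1_mode: str = "printed",
) -> ClassifierReport:
    """Fit the baseline classifier on (X, y) train and report macro F1 on
    (X, y) test.  Test classes absent from the training labels are counted
    per the macro convention (recall 0) and logged."""
    Xtr, ytr = train
    Xte, yte = test
    if len(Xtr) == 0:
        raise ValueError("training set is empty")
    missing = set(pd.unique(np.asarray(yte))) - set(pd.unique(np.asarray(ytr)))
    if missing:
        logger.warning("test classes absent from training data: %s", sorted(missing))
    clf = _make_classifier(classifier_spec)
    clf.fit(np.asarray(Xtr, dtype=float), np.asarray(ytr))
    pred = clf.predict(np.asarray(Xte, dtype=float))
    P, R, F1 = precision_recall_f1(yte, pred, f1_mode=f1_mode)
    return ClassifierReport(P, R, F1, n_train=len(Xtr), n_test=len(Xte))
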