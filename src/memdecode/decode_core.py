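"""Normalization, feature selection, the linear classifier, and the
cross-validation engines shared by the searchlight, regional and temporal
analyses.

Two normalizations mirror the decoding pipeline's two concerns: a spatial
z-score of each sample across features removes the overall activity level
(classification must use the spatial distribution of activity), and a
per-feature detrend + z-score across trials removes slow drifts in single
trial estimates. Classification is a soft-margin linear SVM (hinge loss,
C = 1 by default). Between-subject decoding uses leave-one-subject-out
folds; within-subject decoding uses k run-grouped folds (k = 7 by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "LabeledPatterns",
    "CvScheme",
    "spatial_zscore",
    "detrend_zscore_trials",
    "anova_select",
    "LinearDecisionFunction",
    "fit_linear_classifier",
    "cross_validate",
    "CvResult",
    "balanced_subsample",
]


@dataclass
class LabeledPatterns:
    """Samples x features with binary labels and per-sample metadata."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.subject_ids = np.asarray(self.subject_ids)
        if len(self.y) != self.X.shape[0] or len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("labels/subject_ids must align with rows of X")
        if len(np.unique(self.y)) != 2:
            raise ValueError("exactly two classes are required")
        if self.meta is not None and len(self.meta) != self.X.shape[0]:
            raise ValueError("meta must align with rows of X")

    def subset(self, idx: np.ndarray) -> "LabeledPatterns":
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return LabeledPatterns(self.X[idx], self.y[idx], self.subject_ids[idx], meta)


@dataclass(frozen=True)
class CvScheme:
    """Cross-validation layout: LOSO across subjects or k folds within one."""

    kind: str = "leave_one_subject_out"
    k: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_subject_out", "k_fold_within"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")


def spatial_zscore(X: np.ndarray) -> np.ndarray:
    """Z-score each sample (row) across its features.

    Removes the overall activity level per map so classifiers see only the
    spatial distribution of activity. Invariant to adding a constant to a
    map or rescaling it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < 2:
        raise ValueError("need at least two features to z-score a map")
    sd = X.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance map cannot be z-scored")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def detrend_zscore_trials(X: np.ndarray) -> np.ndarray:
    """Remove a linear trend across trials per feature, then z-score.

    Constant (or perfectly linear) features come back as all zeros with a
    warning rather than NaNs.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least three trials to detrend")
    t = np.arange(n, dtype=float)
    t = (t - t.mean()) / np.linalg.norm(t - t.mean())
    Xc = X - X.mean(axis=0, keepdims=True)
    Xd = Xc - np.outer(t, t @ Xc)
    sd = Xd.std(axis=0, ddof=0)
    flat = sd <= 1e-10 * (np.abs(X).max() + 1.0)
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant feature(s) zeroed in detrend_zscore_trials")
        sd = np.where(flat, 1.0, sd)
    out = Xd / sd
    out[:, flat] = 0.0
    return out


def anova_select(X_train: np.ndarray, y_train: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features with the largest between-class F score.

    Computed on the training rows only; ties (and invalid F values) break
    deterministically toward the lowest feature index.
    """
    from sklearn.feature_selection import f_classif

    X_train = np.asarray(X_train, dtype=float)
    if k > X_train.shape[1]:
        raise ValueError(f"k={k} exceeds {X_train.shape[1]} features")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(X_train, y_train)
    F = np.where(np.isfinite(F), F, -np.inf)
    order = np.argsort(-F, kind="stable")  # stable: ties keep lowest index first
    return np.sort(order[:k])


@dataclass
class LinearDecisionFunction:
    """w·x + b linear rule; ties at exactly 0 go to the first class."""

    weights: np.ndarray
    bias: float
    classes: np.ndarray  # sorted; classes[0] is the negative/"first" class

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X)
        return np.where(d > 0, self.classes[1], self.classes[0])


def fit_linear_classifier(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-4
) -> LinearDecisionFunction:
    """Soft-margin linear SVM (exact hinge-loss QP, penalty ``C``)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    svc = SVC(kernel="linear", C=C, tol=tol)
    svc.fit(np.asarray(X, dtype=float), y)
    return LinearDecisionFunction(svc.coef_.ravel().copy(), float(svc.intercept_[0]), classes)


@dataclass
class CvResult:
    fold_accuracies: np.ndarray
    fold_ids: list  # left-out subject id (LOSO) or fold index (within)
    n_test: np.ndarray
    selected: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())


def _loso_folds(patterns: LabeledPatterns):
    for sid in np.unique(patterns.subject_ids):
        test = patterns.subject_ids == sid
        yield sid, ~test, test


def _within_folds(patterns: LabeledPatterns, k: int):
    """Run-grouped folds: whole runs assigned to folds contiguously."""
    if patterns.meta is not None and "run" in patterns.meta.columns:
        groups = patterns.meta["run"].to_numpy()
    else:
        groups = np.arange(len(patterns.y))  # fall back to trial index blocks
    uniq = np.unique(groups)
    if len(uniq) < k:
        # fewer runs than folds: split trials into k contiguous blocks
        blocks = np.array_split(np.arange(len(patterns.y)), k)
        for i, b in enumerate(blocks):
            test = np.zeros(len(patterns.y), dtype=bool)
            test[b] = True
            yield i, ~test, test
        return
    for i, chunk in enumerate(np.array_split(uniq, k)):
        test = np.isin(groups, chunk)
        yield i, ~test, test


def cross_validate(
    patterns: LabeledPatterns,
    scheme: CvScheme,
    k_select: int | None = None,
    C: float = 1.0,
) -> CvResult:
    """Feature-select on the training fold, fit the SVM, score the test fold.

    Returns per-fold accuracies (one per left-out subject for LOSO, one per
    fold within subject) plus the selected feature indices per fold.
    """
    folds = (
        _loso_folds(patterns)
        if scheme.kind == "leave_one_subject_out"
        else _within_folds(patterns, scheme.k)
    )
    accs, ids, ntest, selected = [], [], [], []
    for fold_id, train, test in folds:
        ytr = patterns.y[train]
        if len(np.unique(ytr)) < 2 or not test.any():
            raise ValueError(f"degenerate fold {fold_id!r}: missing a class or empty test set")
        Xtr, Xte = patterns.X[train], patterns.X[test]
        if k_select is not None:
            k = min(k_select, Xtr.shape[1])
            if k < k_select:
                warnings.warn(
                    f"k_select={k_select} exceeds {Xtr.shape[1]} features; selecting all"
                )
            sel = anova_select(Xtr, ytr, k)
            Xtr, Xte = Xtr[:, sel], Xte[:, sel]
            selected.append(sel)
        clf = fit_linear_classifier(Xtr, ytr, C=C)
        pred = clf.predict(Xte)
        accs.append(float(np.mean(pred == patterns.y[test])))
        ids.append(fold_id)
        ntest.append(int(test.sum()))
    return CvResult(np.array(accs), ids, np.array(ntest), selected)


def balanced_subsample(patterns: LabeledPatterns, fraction: float, seed: int = 0) -> LabeledPatterns:
    """Per subject, retain ``fraction`` of trials with equal class counts.

    The target per-class count is ``round(fraction * min class size)``; the
    retained trials are drawn without replacement with a seeded generator.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return patterns
    rng = np.random.default_rng(seed)
    classes = np.unique(patterns.y)
    keep: list[np.ndarray] = []
    for sid in np.unique(patterns.subject_ids):
        in_subj = np.where(patterns.subject_ids == sid)[0]
        per_class = [in_subj[patterns.y[in_subj] == c] for c in classes]
        n_min = min(len(p) for p in per_class)
        target = int(round(fraction * n_min))
        if target < 1:
            raise ValueError(
                f"subject {sid!r}: a class is too small ({n_min} trials) to balance at fraction {fraction}"
            )
        for p in per_class:
            keep.append(rng.choice(p, size=target, replace=False))
    idx = np.sort(np.concatenate(keep))
    return patterns.subset(idx)
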