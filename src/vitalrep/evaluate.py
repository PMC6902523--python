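"""Classifier suite, cross-validation protocol, and metric/ROC reporting.

Protocol: a stratified 80/20 train/test split; 10-fold stratified
cross-validation inside the training portion (9 folds train, 1 validates) for
fold-level dispersion; the model is then refit on the full training portion
and scored once on the held-out 20%.  Metrics: sensitivity (TPR), specificity
(TNR), F1, accuracy at a 0.5 probability threshold, and ROC/AUC from the
predicted probabilities.  Eight classifiers are benchmarked on the tabular
representations (statistical features, topic vectors); the grid-image
representation is classified by the in-package CNN on the same split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("Adaboost", "DT", "SVM", "LR", "NB", "RF", "MLP", "GBDT")


def make_classifier(name: str, seed: int = 0):
    """Instantiate a named classifier with the benchmark's fixed settings.

    Non-default hyper-parameters: Adaboost 100 estimators; DT gini /
    min_samples_split 2 / min_samples_leaf 1 / min_weight_fraction_leaf 0;
    SVM rbf kernel (probability enabled for ROC); LR l2 penalty; RF 100
    estimators; MLP hidden layers (5, 2); GBDT 200 estimators.
    """
    if name == "Adaboost":
        return AdaBoostClassifier(n_estimators=100, random_state=seed)
    if name == "DT":
        return DecisionTreeClassifier(
            criterion="gini",
            min_samples_split=2,
            min_samples_leaf=1,
            min_weight_fraction_leaf=0.0,
            random_state=seed,
        )
    if name == "SVM":
        # ranked by decision_function; hard labels at 0.5 equal SVC.predict
        return SVC(kernel="rbf", random_state=seed)
    if name == "LR":
        # l2 penalty (the sklearn default; the keyword itself is deprecated)
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "NB":
        return GaussianNB()
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(5, 2), max_iter=2000, random_state=seed)
    if name == "GBDT":
        return GradientBoostingClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def classifier_params(name: str, seed: int = 0) -> dict:
    """Serializable hyper-parameters, for the provenance sidecar."""
    return make_classifier(name, seed).get_params()


def confusion_metrics(y_true, y_pred) -> dict:
    """Sensitivity, specificity, F1 and accuracy of hard 0/1 predictions.

    A metric whose denominator is zero is reported as NaN together with a
    reason under the ``undefined`` key, never silently as 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    undefined = {}
    tpr = tp / (tp + fn) if tp + fn else np.nan
    if tp + fn == 0:
        undefined["TPR"] = "no positive ground-truth samples"
    tnr = tn / (tn + fp) if tn + fp else np.nan
    if tn + fp == 0:
        undefined["TNR"] = "no negative ground-truth samples"
    acc = (tp + tn) / len(y_true) if len(y_true) else np.nan
    precision = tp / (tp + fp) if tp + fp else np.nan
    if not np.isnan(precision) and not np.isnan(tpr) and precision + tpr > 0:
        f1 = 2 * precision * tpr / (precision + tpr)
    else:
        f1 = np.nan
        undefined["F1"] = "precision + recall is zero or undefined"
    return {"TPR": tpr, "TNR": tnr, "F1": f1, "ACC": acc, "undefined": undefined}


def roc_auc(y_true, y_score) -> dict:
    """ROC curve points and trapezoidal AUC.

    AUC equals the probability that a random positive outscores a random
    negative, ties counted one half.  Single-class input is an error.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y_true, y_score)
    return {"fpr": fpr, "tpr": tpr, "auc": float(_trapezoid_auc(fpr, tpr))}


@dataclass
class CVConfig:
    """80/20 outer split + stratified 10-fold CV inside the training portion."""

    test_size: float = 0.2
    n_folds: int = 10
    threshold: float = 0.5
    seed: int = 0


@dataclass
class EvalReport:
    """Benchmark results: one row per (representation, classifier)."""

    rows: list[dict] = field(default_factory=list)
    fold_rows: list[dict] = field(default_factory=list)
    roc_curves: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fold_rows)

    def best(self, representation: str | None = None) -> dict:
        rows = self.rows
        if representation is not None:
            rows = [r for r in rows if r["representation"] == representation]
        return max(rows, key=lambda r: (r["AUC"] if not np.isnan(r["AUC"]) else -1))


def _positive_proba(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    score = clf.decision_function(X)
    return 1.0 / (1.0 + np.exp(-score))  # monotone map; only ranks matter for AUC


def split_cohort(y, cv: CVConfig):
    """Stratified outer train/test indices shared across representations."""
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=cv.test_size, stratify=y, random_state=cv.seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def run_cv(
    features,
    labels,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    cv: CVConfig | None = None,
    representation: str = "features",
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvalReport:
    """Benchmark named classifiers on a feature matrix.

    Per classifier: 10-fold stratified CV inside the 80% training portion
    gives fold-level validation metrics; the classifier is refit on the full
    training portion and scored on the held-out 20% test split.  Deterministic
    given ``cv.seed`` (stochastic classifiers are seeded from it too).
    """
    cv = cv or CVConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    min_class_train = int(np.floor(counts.min() * (1 - cv.test_size)))
    if min_class_train < cv.n_folds:
        raise ValueError(
            f"smallest class has ~{min_class_train} training samples; "
            f"use fewer than {cv.n_folds} folds"
        )
    train_idx, test_idx = split if split is not None else split_cohort(y, cv)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)

    report = EvalReport(
        config={
            "cv": asdict(cv),
            "representation": representation,
            "classifiers": {name: _jsonable(classifier_params(name, cv.seed)) for name in classifiers},
        }
    )
    for name in classifiers:
        base = make_classifier(name, cv.seed)
        for fold, (fit_idx, val_idx) in enumerate(skf.split(X_tr, y_tr)):
            clf = clone(base)
            clf.fit(X_tr[fit_idx], y_tr[fit_idx])
            p_val = _positive_proba(clf, X_tr[val_idx])
            mets = confusion_metrics(y_tr[val_idx], (p_val >= cv.threshold).astype(int))
            try:
                mets["AUC"] = roc_auc(y_tr[val_idx], p_val)["auc"]
            except ValueError:
                mets["AUC"] = np.nan
            mets.pop("undefined")
            report.fold_rows.append(
                {"representation": representation, "classifier": name, "fold": fold, **mets}
            )
        clf = clone(base)
        clf.fit(X_tr, y_tr)
        p_te = _positive_proba(clf, X_te)
        mets = confusion_metrics(y_te, (p_te >= cv.threshold).astype(int))
        roc = roc_auc(y_te, p_te)
        mets.pop("undefined")
        report.rows.append(
            {
                "representation": representation,
                "classifier": name,
                "split": "test",
                **mets,
                "AUC": roc["auc"],
            }
        )
        report.roc_curves[(representation, name)] = roc
    return report


def _jsonable(params: dict) -> dict:
    return {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v)) for k, v in params.items()}


def evaluate_cnn(
    tensors,
    labels,
    cv: CVConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
    cnn_spec=None,
    representation: str = "image",
) -> EvalReport:
    """Train the grid CNN on the shared split and score the held-out test set.

    One stratified fold of the training portion (a 9:1 split) serves as the
    validation set for early stopping; the training curve is kept in the
    report config.
    """
    from .cnn import CNNSpec, train_cnn

    cv = cv or CVConfig()
    spec = cnn_spec or CNNSpec(seed=cv.seed)
    X = np.asarray(tensors, dtype=float)
    y = np.asarray(labels, dtype=int)
    train_idx, test_idx = split if split is not None else split_cohort(y, cv)
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    fit_idx, val_idx = next(
        StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed).split(
            X_tr, y_tr
        )
    )
    model = train_cnn(X_tr[fit_idx], y_tr[fit_idx], spec, X_tr[val_idx], y_tr[val_idx])
    p_te = model.predict_proba(X_te)[:, 1]
    mets = confusion_metrics(y_te, (p_te >= cv.threshold).astype(int))
    roc = roc_auc(y_te, p_te)
    mets.pop("undefined")
    report = EvalReport(
        config={
            "cv": asdict(cv),
            "representation": representation,
            "cnn_spec": asdict(spec),
            "history": asdict(model.history),
        }
    )
    report.rows.append(
        {
            "representation": representation,
            "classifier": "GRCNN",
            "split": "test",
            **mets,
            "AUC": roc["auc"],
        }
    )
    report.roc_curves[(representation, "GRCNN")] = roc
    return report


def benchmark_all(
    cohort,
    cv: CVConfig | None = None,
    lda_topics: int = 5,
    grid_shape: tuple[int, int] = (16, 16),
    cnn_spec=None,
    filter_features: bool = True,
) -> EvalReport:
    """Run all three representation pipelines end-to-end on shared folds.

    Emits 8 statistical-feature rows, 8 text-feature rows and 1 image row
    (the CNN), all scored on the same stratified 80/20 split.
    """
    from .image import cohort_tensors
    from .statistical import correlation_filter, feature_matrix
    from .text import build_corpus, fit_lda, topic_matrix

    cv = cv or CVConfig()
    records = cohort.complete_records()
    label_of = {r.patient_id: r.label for r in records}

    # all three representations are aligned to the id-sorted feature matrix
    stats = feature_matrix(cohort)
    ids = list(stats.index)
    y = np.array([label_of[i] for i in ids], dtype=int)
    split = split_cohort(y, cv)
    if filter_features:
        stats, _ = correlation_filter(stats)
    rep = run_cv(stats.to_numpy(), y, cv=cv, representation="statistical", split=split)

    corpus = build_corpus(cohort)
    topics = topic_matrix(fit_lda(corpus, k=lda_topics, seed=cv.seed), corpus)
    topics = topics.reindex(ids)
    if topics.isna().any().any():
        raise ValueError("text pipeline skipped patients; cannot share folds")
    rep_text = run_cv(topics.to_numpy(), y, cv=cv, representation="text", split=split)

    X_img, _, img_ids = cohort_tensors(cohort, *grid_shape)
    order = [img_ids.index(i) for i in ids]
    rep_img = evaluate_cnn(X_img[order], y, cv=cv, split=split, cnn_spec=cnn_spec)

    combined = EvalReport(
        rows=rep.rows + rep_text.rows + rep_img.rows,
        fold_rows=rep.fold_rows + rep_text.fold_rows,
        roc_curves={**rep.roc_curves, **rep_text.roc_curves, **rep_img.roc_curves},
        config={
            "statistical": rep.config,
            "text": rep_text.config,
            "image": rep_img.config,
            "lda_topics": lda_topics,
            "grid_shape": list(grid_shape),
        },
    )
    return combined
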