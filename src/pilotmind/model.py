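"""Ensemble classification of mental states with stratified 5-fold CV.

`MentalStateClassifier` is the model object: built from cleaned, labelled
epochs (features are re-extracted inside every training fold so that nothing
fitted ever sees validation labels) or directly from a precomputed feature
matrix.  Its `fit()` trains five model families per fold —

* RF:  random forest, 200 trees, entropy split criterion
* ERT: extremely randomized trees, 200 trees, entropy criterion
* GTB: gradient tree boosting, 100 stages, friedman_mse criterion
* AdaBoost: adaptive boosting over decision stumps
* Voting: soft vote — argmax of the unweighted mean of the RF, ERT and GTB
  class-probability outputs

— and returns a `MentalStateResults` holding one `ClassifierReport` per
family: per-class precision/recall/F1 (computed from one-vs-rest TP/FP/TN/FN
counts), macro averages, overall accuracy, fold-wise standard errors of the
per-class F1, and row-normalized confusion matrices in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold

from .features import FeatureExtractor, _class_order
from .preprocess import EpochSet

__all__ = [
    "CVPlan",
    "ClassifierReport",
    "MentalStateClassifier",
    "MentalStateResults",
    "stratified_kfold",
    "make_classifiers",
    "soft_vote",
    "score",
    "VOTING_MEMBERS",
]

VOTING_MEMBERS = ("RF", "ERT", "GTB")


@dataclass(frozen=True)
class CVPlan:
    """Seeded stratified fold assignment: ``folds[i]`` is sample i's
    validation fold, in 0..k-1."""

    folds: np.ndarray
    k: int
    seed: int

    def split(self):
        for f in range(self.k):
            va = np.flatnonzero(self.folds == f)
            tr = np.flatnonzero(self.folds != f)
            yield tr, va


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> CVPlan:
    """Stratified k-fold plan; every sample is validation exactly once and
    per-fold class proportions match the global ones to within one sample."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members; need >= {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for f, (_, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[va] = f
    return CVPlan(folds=folds, k=k, seed=seed)


def make_classifiers(seed: int = 0) -> dict:
    """The four base model families with their pinned hyperparameters."""
    return {
        "RF": RandomForestClassifier(
            n_estimators=200, criterion="entropy", random_state=seed, n_jobs=1
        ),
        "ERT": ExtraTreesClassifier(
            n_estimators=200, criterion="entropy", random_state=seed, n_jobs=1
        ),
        # friedman_mse split criterion is the library default
        "GTB": GradientBoostingClassifier(n_estimators=100, random_state=seed),
        "AdaBoost": AdaBoostClassifier(random_state=seed),
    }


def soft_vote(probability_outputs) -> np.ndarray:
    """Argmax of the unweighted mean of several class-probability matrices;
    exact ties go to the lowest class index."""
    mats = [np.asarray(P, dtype=float) for P in probability_outputs]
    if len({P.shape for P in mats}) != 1:
        raise ValueError("probability matrices must share a shape")
    for P in mats:
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("rows must be probability vectors summing to 1")
    return np.mean(mats, axis=0).argmax(axis=1)


def _counts(y_true, y_pred, cls):
    tp = int(np.sum((y_pred == cls) & (y_true == cls)))
    fp = int(np.sum((y_pred == cls) & (y_true != cls)))
    fn = int(np.sum((y_pred != cls) & (y_true == cls)))
    tn = int(np.sum((y_pred != cls) & (y_true != cls)))
    return tp, fp, fn, tn


def _prf(tp, fp, fn):
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


@dataclass
class ClassifierReport:
    """Per-class and macro metrics (percent) with fold-wise F1 standard errors."""

    classes: list
    per_class: pd.DataFrame  # index class; precision, recall, f1 (%), f1_se
    accuracy: float  # overall, %
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: pd.DataFrame  # row-normalized %, true x predicted
    confusion_counts: pd.DataFrame

    def summary(self, digits: int = 0) -> str:
        lines = [
            "Mental-state classification report",
            f"overall accuracy: {self.accuracy:.{digits}f}%",
            "",
            self.per_class.round(
                {"precision": digits, "recall": digits, "f1": digits, "f1_se": 3}
            ).to_string(),
            "",
            "row-normalized confusion (%):",
            self.confusion.round(2).to_string(),
        ]
        return "\n".join(lines)


def score(predictions, labels, plan: CVPlan | None = None,
          classes=None) -> ClassifierReport:
    """Compute the report from pooled cross-validation predictions.

    Accuracy is the pooled fraction of correct predictions; per-class
    precision/recall/F1 come from one-vs-rest counts; the F1 standard error
    is the across-fold sample standard deviation divided by sqrt(k).
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(labels)
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and labels must align")
    classes = list(classes) if classes is not None else _class_order(y_true)
    for cls in classes:
        if not np.any(y_true == cls) and not np.any(y_pred == cls):
            raise ValueError(f"class {cls!r} absent from labels and predictions")
    rows, f1_se = {}, {}
    for cls in classes:
        tp, fp, fn, tn = _counts(y_true, y_pred, cls)
        p, r, f1 = _prf(tp, fp, fn)
        rows[cls] = {"precision": 100 * p, "recall": 100 * r, "f1": 100 * f1}
    if plan is not None:
        per_fold = {cls: [] for cls in classes}
        for _, va in plan.split():
            for cls in classes:
                tp, fp, fn, _ = _counts(y_true[va], y_pred[va], cls)
                per_fold[cls].append(_prf(tp, fp, fn)[2])
        for cls in classes:
            f1_se[cls] = float(np.std(per_fold[cls], ddof=1) / np.sqrt(plan.k))
    per_class = pd.DataFrame(rows).T
    per_class["f1_se"] = pd.Series(f1_se) if f1_se else np.nan
    counts = pd.DataFrame(
        [[int(np.sum((y_true == t) & (y_pred == p))) for p in classes]
         for t in classes],
        index=classes,
        columns=classes,
    )
    row_sums = counts.sum(axis=1).replace(0, 1)
    confusion = 100.0 * counts.div(row_sums, axis=0)
    return ClassifierReport(
        classes=classes,
        per_class=per_class,
        accuracy=100.0 * float(np.mean(y_true == y_pred)),
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        confusion=confusion,
        confusion_counts=counts,
    )


@dataclass
class MentalStateResults:
    """Cross-validated results: one report per model family, plus the raw
    pooled predictions and the fold plan that produced them."""

    reports: dict  # name -> ClassifierReport
    predictions: dict  # name -> pooled predicted labels
    labels: np.ndarray
    plan: CVPlan

    def report(self, model: str = "Voting") -> ClassifierReport:
        return self.reports[model]

    def macro_table(self) -> pd.DataFrame:
        rows = {
            name: {
                "accuracy": rep.accuracy,
                "precision": rep.macro_precision,
                "recall": rep.macro_recall,
                "f1": rep.macro_f1,
            }
            for name, rep in self.reports.items()
        }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        out = [
            f"{self.plan.k}-fold stratified cross-validation, "
            f"{len(self.labels)} epochs, seed {self.plan.seed}",
            "",
            "macro-averaged metrics (%):",
            self.macro_table().round(1).to_string(),
        ]
        for name, rep in self.reports.items():
            out += ["", f"== {name} ==", rep.summary(digits=1)]
        return "\n".join(out)

    def plot_confusion(self, model: str = "Voting", ax=None):
        """Heatmap of the row-normalized confusion matrix (lazy matplotlib)."""
        import matplotlib.pyplot as plt

        rep = self.reports[model]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(rep.confusion.to_numpy(), cmap="Blues", vmin=0, vmax=100)
        ax.set_xticks(range(len(rep.classes)), rep.classes)
        ax.set_yticks(range(len(rep.classes)), rep.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{model} confusion (%)")
        for i in range(len(rep.classes)):
            for j in range(len(rep.classes)):
                ax.text(j, i, f"{rep.confusion.iat[i, j]:.1f}",
                        ha="center", va="center", fontsize=8)
        ax.figure.colorbar(im, ax=ax)
        return ax


class MentalStateClassifier:
    """Hybrid-ensemble mental-state model over tangent-space EEG features.

    Build from cleaned labelled epochs (the feature pipeline is refitted
    inside every training fold) or, via `from_features`, from an existing
    feature matrix.  ``fit()`` runs the stratified 5-fold protocol and
    returns a `MentalStateResults`.
    """

    def __init__(self, epochs: EpochSet | None = None, *,
                 features: np.ndarray | None = None,
                 labels=None,
                 extractor: FeatureExtractor | None = None,
                 k: int = 5, seed: int = 0):
        if (epochs is None) == (features is None):
            raise ValueError("provide exactly one of epochs or features")
        self.epochs = epochs
        self.features = None if features is None else np.asarray(features, float)
        if epochs is not None:
            self.labels = np.asarray(epochs.labels)
        else:
            if labels is None:
                raise ValueError("labels required with a feature matrix")
            self.labels = np.asarray(labels)
        self.extractor = extractor or FeatureExtractor()
        self.k = k
        self.seed = seed
        if self.features is not None and len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        if self.features is not None and not np.isfinite(self.features).all():
            bad = np.flatnonzero(~np.isfinite(self.features).all(axis=1))
            raise ValueError(f"non-finite features in rows {bad[:10].tolist()}")

    @classmethod
    def from_epochs(cls, eps: EpochSet, **kw) -> "MentalStateClassifier":
        return cls(epochs=eps, **kw)

    @classmethod
    def from_features(cls, X, labels, **kw) -> "MentalStateClassifier":
        return cls(features=X, labels=labels, **kw)

    def fit(self) -> MentalStateResults:
        import copy

        plan = stratified_kfold(self.labels, k=self.k, seed=self.seed)
        classes = _class_order(self.labels)
        n = len(self.labels)
        preds = {name: np.empty(n, dtype=object)
                 for name in (*make_classifiers(), "Voting")}
        for tr, va in plan.split():
            if self.epochs is not None:
                sub = lambda idx: EpochSet(
                    data=self.epochs.data[idx],
                    labels=self.labels[idx],
                    channel_names=self.epochs.channel_names,
                    sample_rate=self.epochs.sample_rate,
                    montage=self.epochs.montage,
                )
                extractor = copy.deepcopy(self.extractor)
                X_tr = extractor.fit(sub(tr))
                X_va = extractor.transform(sub(va))
            else:
                X_tr, X_va = self.features[tr], self.features[va]
            y_tr = self.labels[tr]
            fold_probs = {}
            for name, clf in make_classifiers(self.seed).items():
                clf.fit(X_tr, y_tr)
                # align probability columns to the canonical class order
                prob = clf.predict_proba(X_va)
                order = [list(clf.classes_).index(c) for c in classes]
                prob = prob[:, order]
                fold_probs[name] = prob
                preds[name][va] = np.asarray(classes)[prob.argmax(axis=1)]
            vote = soft_vote([fold_probs[m] for m in VOTING_MEMBERS])
            preds["Voting"][va] = np.asarray(classes)[vote]
        reports = {
            name: score(p.astype(str), self.labels.astype(str), plan, classes)
            for name, p in preds.items()
        }
        return MentalStateResults(
            reports=reports,
            predictions={k: v.astype(str) for k, v in preds.items()},
            labels=self.labels,
            plan=plan,
        )
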