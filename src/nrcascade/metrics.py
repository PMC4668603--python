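"""Evaluation protocol: confusion counts, Sens/Spec/Acc/MCC, ROC/AUC,
stratified k-fold cross-validation and the jackknife (leave-one-out) test.

Binary metrics from a confusion table::

    Sens = TP / (TP + FN)        Spec = TN / (TN + FP)
    Acc  = (TP + TN) / total
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

with the convention MCC = 0 whenever a factor under the square root is
zero.  For the multiclass (subfamily) level, per-class counts come from the
one-vs-rest decomposition: with ``N+(i)`` the size of class i, ``N-(i)``
the size of its complement, ``m_out(i)`` members of i predicted elsewhere
and ``m_in(i)`` non-members predicted as i,

    TP(i) = N+(i) - m_out(i)     FN(i) = m_out(i)
    FP(i) = m_in(i)              TN(i) = N-(i) - m_in(i)

and the same four formulas give per-class Sens/Spec/Acc/MCC.  The overall
sensitivity is total correct / total N; the overall MCC pools the
one-vs-rest counts over classes (micro pooling) before applying the MCC
formula.

Reports round to 4 decimal places when printed; full precision is kept
internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigurationError, ConsistencyError, LabelError, SequenceDomainError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "PerClassCounts",
    "MulticlassReport",
    "binary_metrics",
    "confusion_from_labels",
    "per_class_counts",
    "per_class_metrics",
    "roc_auc",
    "RocResult",
    "kfold_cv",
    "jackknife_cv",
    "CVResult",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.TN + other.TN,
            self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricsReport:
    sens: float
    spec: float
    acc: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {"sens": self.sens, "spec": self.spec, "acc": self.acc, "mcc": self.mcc}
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def __str__(self) -> str:
        parts = [f"{k}={v:.4f}" for k, v in self.to_dict().items()]
        return "MetricsReport(" + ", ".join(parts) + ")"


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def binary_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Sens/Spec/Acc/MCC from a confusion table (see module docstring)."""
    if counts.total == 0:
        raise SequenceDomainError("metrics undefined for zero evaluated samples")
    return MetricsReport(
        sens=_ratio(counts.TP, counts.TP + counts.FN),
        spec=_ratio(counts.TN, counts.TN + counts.FP),
        acc=(counts.TP + counts.TN) / counts.total,
        mcc=_mcc(counts.TP, counts.FP, counts.TN, counts.FN),
        auc=auc,
    )


def confusion_from_labels(y_true, y_pred, positive="1") -> ConfusionCounts:
    """Tally a binary confusion table from parallel label lists."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ConsistencyError("true and predicted label lists differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


@dataclass(frozen=True)
class PerClassCounts:
    """One-vs-rest counts for one class of a multiclass problem."""

    n_pos: int  # N+(i): size of the class
    n_neg: int  # N-(i): size of all other classes
    misses_out: int  # members predicted elsewhere
    misses_in: int  # non-members predicted as this class

    @property
    def confusion(self) -> ConfusionCounts:
        return ConfusionCounts(
            TP=self.n_pos - self.misses_out,
            FN=self.misses_out,
            FP=self.misses_in,
            TN=self.n_neg - self.misses_in,
        )


@dataclass(frozen=True)
class MulticlassReport:
    classes: tuple[str, ...]
    counts: dict[str, PerClassCounts]
    per_class: dict[str, MetricsReport]
    overall_sens: float
    overall_mcc: float
    overall_spec: float = field(default=0.0)
    overall_acc: float = field(default=0.0)

    def to_dict(self) -> dict:
        return {
            "per_class": {c: r.to_dict() for c, r in self.per_class.items()},
            "overall": {
                "sens": self.overall_sens,
                "spec": self.overall_spec,
                "acc": self.overall_acc,
                "mcc": self.overall_mcc,
            },
        }


def per_class_counts(y_true, y_pred, classes: Sequence[str]) -> dict[str, PerClassCounts]:
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ConsistencyError("true and predicted label lists differ in length")
    declared = set(classes)
    for lab in y_true:
        if lab not in declared:
            raise LabelError(f"true label {lab!r} outside declared classes")
    out: dict[str, PerClassCounts] = {}
    n_total = len(y_true)
    for c in classes:
        n_pos = sum(1 for t in y_true if t == c)
        misses_out = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        misses_in = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        out[c] = PerClassCounts(
            n_pos=n_pos, n_neg=n_total - n_pos, misses_out=misses_out, misses_in=misses_in
        )
    return out


def per_class_metrics(y_true, y_pred, classes: Sequence[str]) -> MulticlassReport:
    """Per-class one-vs-rest Sens/Spec/Acc/MCC plus overall metrics.

    Overall Sens is total correct over total N; overall Spec/Acc/MCC apply
    the binary formulas to the micro-pooled one-vs-rest counts summed over
    classes.
    """
    if not classes:
        raise ConfigurationError("classes must be non-empty")
    counts = per_class_counts(y_true, y_pred, classes)
    per_class = {c: binary_metrics(pc.confusion) for c, pc in counts.items()}
    pooled = ConfusionCounts(0, 0, 0, 0)
    for pc in counts.values():
        pooled = pooled + pc.confusion
    total_correct = sum(pc.confusion.TP for pc in counts.values())
    total_n = len(list(y_true))
    pooled_report = binary_metrics(pooled)
    return MulticlassReport(
        classes=tuple(classes),
        counts=counts,
        per_class=per_class,
        overall_sens=_ratio(total_correct, total_n),
        overall_mcc=pooled_report.mcc,
        overall_spec=pooled_report.spec,
        overall_acc=pooled_report.acc,
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def curve_table(self) -> str:
        lines = ["FPR\tTPR"]
        lines += [f"{f:.6f}\t{t:.6f}" for f, t in zip(self.fpr, self.tpr)]
        return "\n".join(lines)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC from real-valued decision scores.

    The AUC equals the Mann-Whitney probability that a random positive
    outscores a random negative, with ties counted 1/2; curve points are
    (FPR, TPR) at every distinct threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([int(v) for v in labels])
    if scores.shape != y.shape:
        raise ConsistencyError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise SequenceDomainError("ROC requires both classes present")
    fpr, tpr, thr = _roc_curve(y, scores)
    return RocResult(auc=float(_trapezoid_auc(fpr, tpr)), fpr=fpr, tpr=tpr, thresholds=thr)


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``fold_assignments[i]`` is the fold in which sample i was held out;
    ``fold_reports`` holds the per-fold report; ``mean`` averages fold
    metrics arithmetically; ``pooled`` is computed from the union of
    held-out predictions (also exposed as ``predictions``).
    """

    task: str
    fold_assignments: np.ndarray
    fold_reports: list
    mean: MetricsReport | MulticlassReport
    pooled: MetricsReport | MulticlassReport
    predictions: np.ndarray

    @property
    def accuracy(self) -> float:
        if self.task == "binary":
            return self.mean.acc
        return self.mean.overall_acc

    @property
    def overall_sens(self) -> float:
        if self.task == "binary":
            return self.mean.sens
        return self.mean.overall_sens


def _default_classifier(config, n_classes: int, seed: int | None):
    from .cascade import SVMConfig  # local import avoids a cycle

    if config is None:
        config = SVMConfig()
    return config.build(seed=seed)


def _splitter(k: int, seed, stratified: bool):
    if stratified:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def _is_binary(labels) -> bool:
    return set(labels) <= {"0", "1", 0, 1}


def _fit_predict(X, y, train, test, config, seed, want_scores):
    clf = _default_classifier(config, len(set(y)), seed)
    clf.fit(X[train], [y[i] for i in train])
    pred = clf.predict(X[test])
    scores = None
    if want_scores:
        scores = clf.decision_function(X[test])
    return pred, scores


def kfold_cv(
    records,
    labels,
    feature_set: str = "aac+ctf",
    k: int = 10,
    seed: int | None = 0,
    config=None,
    stratified: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of an RBF-SVM on encoded features.

    The task is binary when the label set is {0, 1} (Sens/Spec/Acc/MCC and
    AUC per fold), multiclass otherwise (per-class and overall metrics).
    Folds are a seeded random partition; a class with fewer than k members
    triggers a warning and may be absent from some folds.
    """
    from .encode import SequenceEncoder

    labels = [str(lab) for lab in labels]
    n = len(labels)
    if len(list(records)) != n:
        raise ConsistencyError("records and labels differ in length")
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the {n} available samples")
    binary = _is_binary(labels)
    X = SequenceEncoder(feature_set).fit_transform(records)
    y = np.asarray(labels)
    classes = sorted(set(labels))
    splitter = _splitter(k, seed, stratified)
    assignments = np.full(n, -1, dtype=int)
    predictions = np.empty(n, dtype=object)
    fold_reports = []
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        pred, scores = _fit_predict(X, labels, train, test, config, seed, binary)
        assignments[test] = fold
        predictions[test] = pred
        if binary:
            cc = confusion_from_labels(y[test], pred)
            fold_auc = None
            if len(set(y[test])) == 2:
                fold_auc = roc_auc(scores, y[test]).auc
            fold_reports.append(binary_metrics(cc, auc=fold_auc))
        else:
            fold_reports.append(per_class_metrics(y[test], pred, classes))
    if binary:
        aucs = [r.auc for r in fold_reports if r.auc is not None]
        mean = MetricsReport(
            sens=float(np.mean([r.sens for r in fold_reports])),
            spec=float(np.mean([r.spec for r in fold_reports])),
            acc=float(np.mean([r.acc for r in fold_reports])),
            mcc=float(np.mean([r.mcc for r in fold_reports])),
            auc=float(np.mean(aucs)) if aucs else None,
        )
        pooled = binary_metrics(confusion_from_labels(y, predictions))
    else:
        mean_sens = float(np.mean([r.overall_sens for r in fold_reports]))
        pooled_mc = per_class_metrics(y, predictions, classes)
        mean = MulticlassReport(
            classes=tuple(classes),
            counts=pooled_mc.counts,
            per_class=pooled_mc.per_class,
            overall_sens=mean_sens,
            overall_mcc=float(np.mean([r.overall_mcc for r in fold_reports])),
            overall_spec=float(np.mean([r.overall_spec for r in fold_reports])),
            overall_acc=float(np.mean([r.overall_acc for r in fold_reports])),
        )
        pooled = pooled_mc
    return CVResult(
        task="binary" if binary else "multiclass",
        fold_assignments=assignments,
        fold_reports=fold_reports,
        mean=mean,
        pooled=pooled,
        predictions=predictions,
    )


def jackknife_cv(records, labels, feature_set: str = "aac+ctf", config=None) -> CVResult:
    """Leave-one-out test: N training rounds, each tested on the left-out
    sample; deterministic (no seed) and invariant to input order.  Metrics
    are reported from the pooled confusion of the N single-sample tests."""
    from .encode import SequenceEncoder

    labels = [str(lab) for lab in labels]
    n = len(labels)
    if n < 3:
        raise ConfigurationError("jackknife needs at least 3 samples")
    binary = _is_binary(labels)
    X = SequenceEncoder(feature_set).fit_transform(records)
    y = np.asarray(labels)
    classes = sorted(set(labels))
    predictions = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        train = idx[idx != i]
        pred, _ = _fit_predict(X, labels, train, np.array([i]), config, None, False)
        predictions[i] = pred[0]
    if binary:
        pooled = binary_metrics(confusion_from_labels(y, predictions))
    else:
        pooled = per_class_metrics(y, predictions, classes)
    return CVResult(
        task="binary" if binary else "multiclass",
        fold_assignments=idx.copy(),
        fold_reports=[],
        mean=pooled,
        pooled=pooled,
        predictions=predictions,
    )
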