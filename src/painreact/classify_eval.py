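"""Classifiers, class balancing, metrics and the two cross-validation schemes.

Two subject-dependent classifiers are evaluated: an AdaBoost ensemble of
depth-limited decision trees (SAMME weight updates, which reduce to the
classic binary AdaBoost for two classes) and a soft-margin SVM with a
Gaussian kernel (binary tasks only; its multiclass performance is not
competitive on this problem).  Four tasks are defined — the three pairwise
binary problems and the three-class problem — and each is evaluated under
two schemes: pooled, stratified 10-fold cross-validation and one-patient-out
(leave-one-subject-out).  Class balance is maintained by random
undersampling to the minority class, re-drawn independently for each of the
repeated runs; results aggregate mean and sd of five metrics (accuracy,
sensitivity, precision, specificity, F1) over folds x runs, per class for
the multiclass task.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .pain_labeling import PainClass

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity", "f1")

#: task name -> (classes involved, positive class); multiclass keeps all.
TASKS = {
    "sev_vs_no": ((PainClass.SEVERE_PAIN, PainClass.NO_PAIN),
                  PainClass.SEVERE_PAIN),
    "sev_vs_mod": ((PainClass.SEVERE_PAIN, PainClass.MODERATE_PAIN),
                   PainClass.SEVERE_PAIN),
    "mod_vs_no": ((PainClass.MODERATE_PAIN, PainClass.NO_PAIN),
                  PainClass.MODERATE_PAIN),
    "multiclass": ((PainClass.NO_PAIN, PainClass.MODERATE_PAIN,
                    PainClass.SEVERE_PAIN), None),
}


class UnsupportedTaskError(ValueError):
    """The classifier does not support this task (e.g. multiclass SVM)."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters for either classifier.

    AdaBoost trees are limited to ``max_branch_nodes`` split nodes (i.e.
    ``max_branch_nodes + 1`` leaves).  The SVM kernel scale defaults to the
    median pairwise distance heuristic when left unset.
    """

    kind: str = "adaboost"
    n_learners: int = 100
    max_branch_nodes: int = 20
    learning_rate: float = 1.0
    box_constraint: float = 1.0
    kernel_scale: float | None = None

    def __post_init__(self):
        if self.kind not in ("adaboost", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.n_learners < 1 or self.max_branch_nodes < 1:
            raise ValueError("n_learners and max_branch_nodes must be >= 1")


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    precision: float
    specificity: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(y_true, y_pred, positive_class) -> Metrics:
    """Confusion-matrix metrics with ``positive_class`` one-vs-rest.

    ``accuracy = (TP+TN)/N``, ``sensitivity = TP/(TP+FN)``,
    ``precision = TP/(TP+FP)``, ``specificity = TN/(TN+FP)``,
    ``F1 = 2*prec*sens/(prec+sens)``.  A zero denominator yields 0 and the
    metric name is recorded in ``undefined``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    prec = ratio(tp, tp + fp, "precision")
    spec = ratio(tn, tn + fp, "specificity")
    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    return Metrics(accuracy=acc, sensitivity=sens, precision=prec,
                   specificity=spec, f1=f1, undefined=tuple(undefined))


def train_adaboost(X, y, spec: ClassifierSpec = ClassifierSpec(),
                   seed: int = 0) -> AdaBoostClassifier:
    """Boosted depth-limited trees; SAMME handles binary and multiclass."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    model = AdaBoostClassifier(
        estimator=DecisionTreeClassifier(
            max_leaf_nodes=spec.max_branch_nodes + 1, random_state=seed),
        n_estimators=spec.n_learners,
        learning_rate=spec.learning_rate,
        random_state=seed,
    )
    return model.fit(np.asarray(X), y)


def median_distance_scale(X, max_points: int = 500, seed: int = 0) -> float:
    """Median pairwise Euclidean distance (on a subsample for large X)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], max_points, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    vals = np.sqrt(d2[np.triu_indices_from(d2, k=1)])
    med = float(np.median(vals)) if vals.size else 1.0
    return med if med > 0 else 1.0


def train_svm(X, y, spec: ClassifierSpec = ClassifierSpec(kind="svm")) -> SVC:
    """Soft-margin Gaussian-kernel SVM for binary tasks only."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise UnsupportedTaskError(
            f"SVM evaluation is binary-only; got {classes.size} classes")
    scale = (spec.kernel_scale if spec.kernel_scale is not None
             else median_distance_scale(X))
    model = SVC(kernel="rbf", C=spec.box_constraint,
                gamma=1.0 / (2.0 * scale ** 2))
    return model.fit(np.asarray(X), y)


def train_classifier(X, y, spec: ClassifierSpec, seed: int = 0):
    if spec.kind == "adaboost":
        return train_adaboost(X, y, spec, seed)
    return train_svm(X, y, spec)


def balance_classes(labels, seed, classes=None) -> np.ndarray:
    """Indices of a random undersample equalizing counts across ``classes``.

    ``classes`` defaults to the classes present; a required class with no
    frames raises, naming the class.  Deterministic per seed; the returned
    indices are sorted.
    """
    labels = np.asarray(labels)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if classes is None:
        classes = np.unique(labels)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    for c, n in counts.items():
        if n == 0:
            name = PainClass(c).name.lower() if c in list(PainClass) else c
            raise ValueError(f"class {name!r} has no frames to balance")
    n_min = min(counts.values())
    picked = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        picked.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(picked))


@dataclass(frozen=True)
class CVResult:
    """Mean +- sd of every metric over folds x runs, per class or task."""

    task: str
    scheme: str
    classifier: str
    feature_mode: str
    runs: int
    n_evaluations: int
    #: class-name -> metric-name -> list of per-evaluation values
    raw: dict = field(repr=False, default_factory=dict)

    def mean(self, cls: str, metric: str) -> float:
        return float(np.mean(self.raw[cls][metric]))

    def sd(self, cls: str, metric: str) -> float:
        return float(np.std(self.raw[cls][metric], ddof=1))

    def macro_f1(self) -> float:
        return float(np.mean([self.mean(c, "f1") for c in self.raw]))

    def summary(self) -> pd.DataFrame:
        rows = []
        for cls in self.raw:
            for m in METRIC_NAMES:
                rows.append({"class": cls, "metric": m,
                             "mean": round(self.mean(cls, m), 4),
                             "sd": round(self.sd(cls, m), 4)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "experiment": {"task": self.task, "scheme": self.scheme,
                           "classifier": self.classifier,
                           "feature_mode": self.feature_mode,
                           "runs": self.runs,
                           "n_evaluations": self.n_evaluations},
            "metrics": {cls: {m: {"mean": round(self.mean(cls, m), 6),
                                  "sd": round(self.sd(cls, m), 6)}
                              for m in METRIC_NAMES}
                        for cls in self.raw},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 1)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def _class_name(c) -> str:
    return PainClass(int(c)).name.lower()


def _evaluate_split(model, X_test, y_test, task: str) -> dict:
    y_pred = model.predict(X_test)
    classes, positive = TASKS[task]
    if positive is not None:
        return {_class_name(positive):
                compute_metrics(y_test, y_pred, int(positive))}
    return {_class_name(c): compute_metrics(y_test, y_pred, int(c))
            for c in classes}


def run_cv(X, y, subjects, task: str, scheme: str,
           classifier: ClassifierSpec = ClassifierSpec(),
           runs: int = 10, seed: int = 0,
           feature_mode: str = "scattering") -> CVResult:
    """Run one experiment: a task under a validation scheme, repeated.

    ``kfold10`` pools the balanced frames of all subjects and splits them
    into 10 stratified folds; ``one_patient_out`` holds each subject's
    frames out in turn, rebalancing the remaining training pool.  Every run
    re-draws the balanced subset.  A test subject missing one of the task's
    classes is skipped with a logged warning.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if scheme not in ("kfold10", "one_patient_out"):
        raise ValueError(f"unknown scheme {scheme!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    subjects = np.asarray(subjects)
    if scheme == "one_patient_out" and np.unique(subjects).size < 2:
        raise ValueError("one_patient_out needs at least 2 subjects")
    task_classes = [int(c) for c in TASKS[task][0]]
    if classifier.kind == "svm" and len(task_classes) > 2:
        raise UnsupportedTaskError("SVM evaluation is binary-only")

    in_task = np.isin(y, task_classes)
    Xt, yt, st = X[in_task], y[in_task], subjects[in_task]

    collected: dict[str, dict[str, list[float]]] = {}
    n_eval = 0
    for run in range(runs):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, run])
        bal = balance_classes(yt, rng, classes=task_classes)
        Xb, yb, sb = Xt[bal], yt[bal], st[bal]
        fold_seed = int(rng.integers(2 ** 31 - 1))

        if scheme == "kfold10":
            splitter = StratifiedKFold(n_splits=10, shuffle=True,
                                       random_state=fold_seed)
            splits = splitter.split(Xb, yb)
        else:
            splits = _one_patient_out_splits(yb, sb, task_classes, rng)

        for train_idx, test_idx in splits:
            model = train_classifier(Xb[train_idx], yb[train_idx],
                                     classifier, seed=fold_seed)
            for cls, metrics in _evaluate_split(
                    model, Xb[test_idx], yb[test_idx], task).items():
                bucket = collected.setdefault(
                    cls, {m: [] for m in METRIC_NAMES})
                for m in METRIC_NAMES:
                    bucket[m].append(getattr(metrics, m))
            n_eval += 1

    return CVResult(task=task, scheme=scheme, classifier=classifier.kind,
                    feature_mode=feature_mode, runs=runs,
                    n_evaluations=n_eval, raw=collected)


def _one_patient_out_splits(y, subjects, task_classes, rng):
    """Leave-one-subject-out on the balanced pool, rebalancing training."""
    for subj in pd.unique(subjects):
        test_idx = np.flatnonzero(subjects == subj)
        present = set(np.unique(y[test_idx]).tolist())
        if not set(task_classes) <= present:
            missing = [_class_name(c) for c in task_classes
                       if c not in present]
            logger.warning("one_patient_out: subject %s skipped, missing "
                           "class(es) %s in its test frames", subj, missing)
            continue
        train_idx = np.flatnonzero(subjects != subj)
        rebal = balance_classes(y[train_idx], rng, classes=task_classes)
        yield train_idx[rebal], test_idx
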