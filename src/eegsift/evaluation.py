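"""Repeated 70/30 hold-out evaluation of the linear SVM, and reporting.

Each repetition draws a fresh stratified train/test split (largest-remainder
rounding of per-class counts), fits the linear SVM on the training set and
scores both sets. Accuracies, true-positive/negative rates and confusion
counts are averaged over repetitions. The distress contrast splits patients
at TQ < 30 (low) and TQ > 38 (high), excluding scores in between.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .cohort import SubjectRecord
from .selection import make_svm


@dataclass
class DistressGrouping:
    """Patients split by TQ distress score: low (<30), high (>38), excluded."""

    low_ids: list[str]
    high_ids: list[str]
    excluded_ids: list[str]


def assign_distress_groups(records: list[SubjectRecord]) -> DistressGrouping:
    """Split patient records into low / high / excluded distress strata."""
    low, high, excl = [], [], []
    for r in records:
        if r.tq_score is None:
            raise ValueError(f"subject {r.subject_id} has no TQ score")
        if r.tq_score < 30:
            low.append(r.subject_id)
        elif r.tq_score > 38:
            high.append(r.subject_id)
        else:
            excl.append(r.subject_id)
    return DistressGrouping(low, high, excl)


@dataclass
class ClassifierReport:
    """Averages over repeated hold-out splits.

    Confusion matrices are mean counts with rows = actual class
    (negative, positive) and columns = predicted class; rates are row-
    normalized diagonal entries. Positive = the condition of interest
    (patients in the control/patient contrast, high distress in the
    low/high contrast).
    """

    mean_train_accuracy: float
    mean_test_accuracy: float
    train_tpr: float
    train_tnr: float
    test_tpr: float
    test_tnr: float
    confusion_train: np.ndarray
    confusion_test: np.ndarray
    n_reps: int
    n_train: tuple[int, int] = (0, 0)  # (negatives, positives)
    n_test: tuple[int, int] = (0, 0)
    class_names: tuple[str, str] = ("negative", "positive")

    def to_dict(self) -> dict:
        return {
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_test_accuracy": self.mean_test_accuracy,
            "train_tpr": self.train_tpr,
            "train_tnr": self.train_tnr,
            "test_tpr": self.test_tpr,
            "test_tnr": self.test_tnr,
            "confusion_train": np.asarray(self.confusion_train).tolist(),
            "confusion_test": np.asarray(self.confusion_test).tolist(),
            "n_reps": self.n_reps,
            "n_train": list(self.n_train),
            "n_test": list(self.n_test),
            "class_names": list(self.class_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierReport":
        return cls(
            mean_train_accuracy=d["mean_train_accuracy"],
            mean_test_accuracy=d["mean_test_accuracy"],
            train_tpr=d["train_tpr"],
            train_tnr=d["train_tnr"],
            test_tpr=d["test_tpr"],
            test_tnr=d["test_tnr"],
            confusion_train=np.asarray(d["confusion_train"]),
            confusion_test=np.asarray(d["confusion_test"]),
            n_reps=d["n_reps"],
            n_train=tuple(d["n_train"]),
            n_test=tuple(d["n_test"]),
            class_names=tuple(d["class_names"]),
        )


def _largest_remainder_counts(n_per_class: np.ndarray, frac: float) -> np.ndarray:
    """Per-class training counts: largest-remainder rounding of frac*n."""
    exact = n_per_class * frac
    base = np.floor(exact).astype(int)
    short = int(np.floor(exact.sum())) - base.sum()
    order = np.argsort(-(exact - base))
    for i in range(short):
        base[order[i]] += 1
    base = np.clip(base, 1, n_per_class - 1)  # both sets need every class
    return base


class RepeatedHoldoutEvaluator:
    """Repeated stratified hold-out training/testing of the linear SVM.

    Parameters mirror the study protocol: 70% training fraction and 5000
    repetitions by default. A fixed ``random_state`` reproduces the exact
    sequence of splits and hence the report.
    """

    def __init__(self, train_frac: float = 0.7, n_reps: int = 5000,
                 C: float = 1.0, random_state: int | None = None):
        if not (0 < train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.train_frac = train_frac
        self.n_reps = n_reps
        self.C = C
        self.random_state = random_state

    def evaluate(self, X, y, class_names: tuple[str, str] = ("negative", "positive")
                 ) -> ClassifierReport:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("hold-out evaluation requires two classes")
        # class 0 = negative, class 1 = positive (sorted label order)
        idx_by_class = [np.flatnonzero(y == c) for c in classes]
        n_per_class = np.array([len(ix) for ix in idx_by_class])
        if (n_per_class < 2).any():
            raise ValueError("need at least two subjects per class")
        n_train = _largest_remainder_counts(n_per_class, self.train_frac)
        rng = np.random.default_rng(self.random_state)

        conf_tr = np.zeros((2, 2))
        conf_te = np.zeros((2, 2))
        acc_tr = acc_te = 0.0
        for _ in range(self.n_reps):
            tr_idx, te_idx = [], []
            for ix, k in zip(idx_by_class, n_train):
                perm = rng.permutation(ix)
                tr_idx.append(perm[:k])
                te_idx.append(perm[k:])
            tr = np.concatenate(tr_idx)
            te = np.concatenate(te_idx)
            clf = make_svm(self.C).fit(X[tr], y[tr])
            for sel, conf in ((tr, conf_tr), (te, conf_te)):
                pred = clf.predict(X[sel])
                for a, cls_a in enumerate(classes):
                    mask = y[sel] == cls_a
                    for b, cls_b in enumerate(classes):
                        conf[a, b] += (pred[mask] == cls_b).sum()
            acc_tr += (clf.predict(X[tr]) == y[tr]).mean()
            acc_te += (clf.predict(X[te]) == y[te]).mean()
        conf_tr /= self.n_reps
        conf_te /= self.n_reps
        n_test = n_per_class - n_train
        return ClassifierReport(
            mean_train_accuracy=acc_tr / self.n_reps,
            mean_test_accuracy=acc_te / self.n_reps,
            train_tpr=conf_tr[1, 1] / n_train[1],
            train_tnr=conf_tr[0, 0] / n_train[0],
            test_tpr=conf_te[1, 1] / n_test[1],
            test_tnr=conf_te[0, 0] / n_test[0],
            confusion_train=conf_tr,
            confusion_test=conf_te,
            n_reps=self.n_reps,
            n_train=(int(n_train[0]), int(n_train[1])),
            n_test=(int(n_test[0]), int(n_test[1])),
            class_names=class_names,
        )


def holdout_evaluate(X, y, train_frac: float = 0.7, n_reps: int = 5000,
                     rng: int | None = None,
                     class_names: tuple[str, str] = ("negative", "positive")
                     ) -> ClassifierReport:
    """Functional wrapper over :class:`RepeatedHoldoutEvaluator`."""
    ev = RepeatedHoldoutEvaluator(train_frac=train_frac, n_reps=n_reps,
                                  random_state=rng)
    return ev.evaluate(X, y, class_names=class_names)


def _confusion_text(conf: np.ndarray, totals: tuple[int, int],
                    names: tuple[str, str]) -> str:
    """Confusion table: clinical assessment rows, prediction columns,
    percentages with mean subject counts in brackets."""
    lines = [f"{'':>24s} {'pred ' + names[0]:>20s} {'pred ' + names[1]:>20s}"]
    for a in range(2):
        row_n = totals[a]
        cells = []
        for b in range(2):
            pct = 100.0 * conf[a, b] / row_n if row_n else 0.0
            cells.append(f"{pct:6.1f}% ({conf[a, b]:6.1f})")
        lines.append(f"{names[a] + f' ({row_n})':>24s} {cells[0]:>20s} {cells[1]:>20s}")
    return "\n".join(lines)


def render_report(rep: ClassifierReport) -> str:
    """Plain-text summary: accuracies plus train/test confusion tables."""
    out = [
        f"repetitions: {rep.n_reps}",
        f"mean training accuracy: {100 * rep.mean_train_accuracy:.1f}%",
        f"mean test accuracy:     {100 * rep.mean_test_accuracy:.1f}%",
        f"train TPR {100 * rep.train_tpr:.1f}%  TNR {100 * rep.train_tnr:.1f}%",
        f"test  TPR {100 * rep.test_tpr:.1f}%  TNR {100 * rep.test_tnr:.1f}%",
        "",
        "training set:",
        _confusion_text(rep.confusion_train, rep.n_train, rep.class_names),
        "",
        "test set:",
        _confusion_text(rep.confusion_test, rep.n_test, rep.class_names),
    ]
    return "\n".join(out)


def report(rep: ClassifierReport, path: str) -> None:
    """Write the report as JSON (lossless) plus a text summary next to it."""
    with open(path, "w") as f:
        json.dump(rep.to_dict(), f, indent=2, sort_keys=True)
    with open(str(path) + ".txt", "w") as f:
        f.write(render_report(rep) + "\n")


def load_report(path: str) -> ClassifierReport:
    with open(path) as f:
        return ClassifierReport.from_dict(json.load(f))
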