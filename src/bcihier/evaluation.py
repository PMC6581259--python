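"""Metrics, the 5-run evaluation protocol and the supervised baselines.

Accuracy is trace/total of a confusion matrix; the false-positive rate
treats intentional control as the positive class, FPR = FP / (FP + TN),
where FP counts NC instances flagged as any IC class.  Dispersion across
runs is reported as the sample standard deviation (n - 1 denominator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io import ALL_CLASSES, IC_CLASSES, NC
from .hierarchy import IC, collapse_ic


def confusion(truth, preds, classes) -> np.ndarray:
    """Counts[i, j] = #(truth = classes[i], predicted = classes[j])."""
    truth, preds = np.asarray(truth), np.asarray(preds)
    known = set(classes)
    for arr, what in ((truth, "truth"), (preds, "prediction")):
        bad = set(arr) - known
        if bad:
            raise ValueError(f"unknown {what} label(s): {sorted(bad)}")
    return _sk_confusion(truth, preds, labels=list(classes))


def accuracy(cm: np.ndarray) -> float:
    """Percent correct from a confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm) / total


def fpr(cm: np.ndarray, classes, nc_label: str = NC) -> float:
    """Percent FPR with IC as the positive class.

    Multi-class matrices are collapsed: every non-NC column counts toward
    the false positives of the NC row.
    """
    classes = list(classes)
    if nc_label not in classes:
        raise ValueError(f"no {nc_label!r} row in the matrix")
    cm = np.asarray(cm)
    i = classes.index(nc_label)
    tn = cm[i, i]
    fp = cm[i].sum() - tn
    if fp + tn == 0:
        raise ValueError("FPR undefined: no NC instances evaluated")
    return 100.0 * fp / (fp + tn)


@dataclass
class CVProtocol:
    """5-run, 10-fold cross-validation protocol parameters."""

    n_runs: int = 5
    n_folds: int = 10
    seed: int = 0


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    direction: str                # "a>b" | "b>a" | "none"
    n_used: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def wilcoxon_compare(a, b, alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired Wilcoxon signed-rank test on per-fold scores.

    Zero differences are dropped (Wilcoxon's rule); all-zero differences
    yield a no-test result with p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 6:
        raise ValueError("need equal-length paired samples, n >= 6")
    d = a - b
    nz = d != 0
    if not nz.any():
        return ComparisonResult(np.nan, 1.0, "none", 0, alpha)
    stat, p = scipy.stats.wilcoxon(a[nz], b[nz], zero_method="wilcox")
    direction = "a>b" if d.mean() > 0 else "b>a" if d.mean() < 0 else "none"
    return ComparisonResult(float(stat), float(p), direction,
                            int(nz.sum()), alpha)


# ---------------------------------------------------------------------------
# report object


def _mean_sd(values) -> tuple:
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


@dataclass
class EvaluationReport:
    """Results object: per-run metrics, their dispersion and diagnostics.

    ``per_run`` has one row per protocol run with the overall accuracy and
    FPR plus the level-wise accuracies; confusion matrices are stored as
    real-valued means over runs (display rounding only).
    """

    per_run: pd.DataFrame
    level1_confusion: np.ndarray     # 2x2 mean, rows/cols (ic, nc)
    level2_confusion: np.ndarray     # 4x4 mean over IC_CLASSES
    overall_confusion: np.ndarray    # 5x5 mean over ALL_CLASSES
    config: dict
    chosen_k: int
    chosen_threshold: float
    grid: object = None              # GridResult when the search ran
    n_selected_features: float = np.nan
    subject_id: str = ""

    @property
    def accuracy(self):
        return _mean_sd(self.per_run["accuracy"])[0]

    @property
    def accuracy_sd(self):
        return _mean_sd(self.per_run["accuracy"])[1]

    @property
    def fpr(self):
        return _mean_sd(self.per_run["fpr"])[0]

    @property
    def fpr_sd(self):
        return _mean_sd(self.per_run["fpr"])[1]

    @property
    def level2_accuracy(self):
        return _mean_sd(self.per_run["level2_accuracy"].dropna())[0]

    def summary(self) -> str:
        lines = []
        title = "Hierarchical BCI evaluation"
        if self.subject_id:
            title += f" - subject {self.subject_id}"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"runs: {len(self.per_run)}    "
                     f"K = {self.chosen_k}    "
                     f"IC threshold = {self.chosen_threshold:.0%}    "
                     f"selected features (mean) = "
                     f"{self.n_selected_features:.1f}")
        lines.append("")
        lines.append(f"{'metric':<28}{'mean':>8}{'sd':>8}")
        lines.append("-" * 44)
        for name, col in (("overall accuracy (%)", "accuracy"),
                          ("FPR (%)", "fpr"),
                          ("level-1 accuracy (%)", "level1_accuracy"),
                          ("level-2 accuracy (%)", "level2_accuracy")):
            m, s = _mean_sd(self.per_run[col].dropna())
            lines.append(f"{name:<28}{m:>8.1f}{s:>8.1f}")
        lines.append("")
        lines.append("mean level-1 confusion (rows true ic/nc):")
        for row in np.round(self.level1_confusion, 1):
            lines.append("  " + "  ".join(f"{v:6.1f}" for v in row))
        lines.append("mean level-2 confusion "
                     f"(rows true {'/'.join(IC_CLASSES)}):")
        for row in np.round(self.level2_confusion, 1):
            lines.append("  " + "  ".join(f"{v:6.1f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "accuracy": self.accuracy, "accuracy_sd": self.accuracy_sd,
            "fpr": self.fpr, "fpr_sd": self.fpr_sd,
            "chosen_k": int(self.chosen_k),
            "chosen_threshold": float(self.chosen_threshold),
            "n_selected_features": float(self.n_selected_features),
            "per_run": self.per_run.to_dict(orient="list"),
            "level1_confusion": self.level1_confusion.tolist(),
            "level2_confusion": self.level2_confusion.tolist(),
            "overall_confusion": self.overall_confusion.tolist(),
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1)

    def to_markdown(self) -> str:
        d = self.to_dict()
        md = [f"# Evaluation report {self.subject_id}".rstrip(), ""]
        md.append(f"- overall accuracy: {d['accuracy']:.1f} "
                  f"± {d['accuracy_sd']:.1f} %")
        md.append(f"- FPR: {d['fpr']:.1f} ± {d['fpr_sd']:.1f} %")
        md.append(f"- K = {d['chosen_k']}, IC threshold = "
                  f"{d['chosen_threshold']:.0%}")
        md.append("")
        md.append("```\n" + self.summary() + "\n```")
        return "\n".join(md)

    def plot_grid(self, ax=None):
        """Accuracy-vs-K curves per IC threshold (needs a grid search)."""
        if self.grid is None:
            raise ValueError("no grid search stored in this report")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for t, sub in self.grid.table.groupby("ic_threshold"):
            ax.plot(sub.K, sub.accuracy, marker="o", label=f"t={t:.2f}")
        ax.set_xlabel("K")
        ax.set_ylabel("CV accuracy (%)")
        ax.legend(fontsize="x-small")
        return ax


def make_classifier(name: str, seed: int = 0, knn_k: int = 5,
                    svm_c: float = 1.0):
    """Factory for the supervised baseline classifiers."""
    if name == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel="linear", C=svm_c))])
    if name == "knn":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(n_neighbors=knn_k))])
    if name == "nb":
        return GaussianNB()
    if name == "tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown baseline classifier {name!r}")
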