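"""The two-level hierarchical classifier and its parameter grid search.

Level 1 is unsupervised: K-means clusters the level-1 training instances
(intentional-control IC and non-intentional-control NC mixed), and each
cluster is labelled IC only if the fraction of IC members reaches the
IC threshold; otherwise it is labelled NC.  New instances are assigned to
the cluster with the smallest average distance to that cluster's stored
members (average linkage; a centroid rule is available) and inherit the
cluster label.  Instances gated through as IC are passed to level 2, a
multiclass soft-margin SVM over the four imagery classes (optionally five,
letting level 2 recover level-1 false positives).

The (K, IC-threshold) pair is chosen by a grid search that maximises
cross-validated accuracy subject to the false-positive-rate bound that makes
a BCI usable in practice (default 10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix
from .io import IC_CLASSES, NC
from .selection import SelectionMask

IC = "ic"

DEFAULT_K_GRID = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)
DEFAULT_T_GRID = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


def collapse_ic(labels) -> np.ndarray:
    """Map 5-class labels to the binary {ic, nc} alphabet."""
    labels = np.asarray(labels)
    return np.where(labels == NC, NC, IC)


def label_clusters(assignments: np.ndarray, is_ic: np.ndarray,
                   k: int, ic_threshold: float) -> np.ndarray:
    """Boolean per-cluster IC labels under the IC-threshold rule (>=)."""
    out = np.zeros(k, dtype=bool)
    for c in range(k):
        m = assignments == c
        if m.any():
            out[c] = is_ic[m].mean() >= ic_threshold
    return out


@dataclass
class Level1Model:
    """Fitted K-means gate with threshold-labelled clusters.

    Features are min-max normalized with training statistics before any
    Euclidean distance is taken (the convention of the clustering tool the
    method was developed with); centroids and stored members live in the
    normalized space.
    """

    k: int
    centroids: np.ndarray          # (k, d), normalized space
    member_x: np.ndarray           # (n, d) training rows, normalized
    member_cluster: np.ndarray     # (n,)
    member_is_ic: np.ndarray       # (n,) bool
    cluster_is_ic: np.ndarray      # (k,) bool
    ic_threshold: float
    col_min: np.ndarray = None     # (d,) training minima
    col_range: np.ndarray = None   # (d,) training ranges (0 -> 1)
    assignment_rule: str = "average"
    seed: int = 0

    def normalize(self, X: np.ndarray) -> np.ndarray:
        if self.col_min is None:
            return X
        return (X - self.col_min) / self.col_range

    @property
    def ic_fractions(self) -> np.ndarray:
        return np.array([self.member_is_ic[self.member_cluster == c].mean()
                         if (self.member_cluster == c).any() else 0.0
                         for c in range(self.k)])

    def relabel(self, ic_threshold: float) -> "Level1Model":
        """Same clustering, new threshold (cheap re-labelling)."""
        return Level1Model(
            self.k, self.centroids, self.member_x, self.member_cluster,
            self.member_is_ic,
            label_clusters(self.member_cluster, self.member_is_ic,
                           self.k, ic_threshold),
            ic_threshold, self.col_min, self.col_range,
            self.assignment_rule, self.seed)


def fit_level1(train1: FeatureMatrix, k: int, ic_threshold: float = 0.8,
               seed: int = 0, assignment_rule: str = "average",
               n_init: int = 10) -> Level1Model:
    """Cluster the IC+NC training rows and threshold-label the clusters."""
    X = train1.values
    if k > len(X):
        raise ValueError(f"K={k} exceeds the {len(X)} training rows")
    if not 0 < ic_threshold <= 1:
        raise ValueError("ic_threshold must be in (0, 1]")
    if assignment_rule not in ("average", "centroid"):
        raise ValueError(f"unknown assignment rule {assignment_rule!r}")
    col_min = X.min(axis=0)
    col_range = X.max(axis=0) - col_min
    col_range = np.where(col_range == 0, 1.0, col_range)
    Xn = (X - col_min) / col_range
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Xn)
    is_ic = collapse_ic(train1.labels) == IC
    assign = km.labels_
    return Level1Model(
        k=k, centroids=km.cluster_centers_, member_x=Xn,
        member_cluster=assign, member_is_ic=is_ic,
        cluster_is_ic=label_clusters(assign, is_ic, k, ic_threshold),
        ic_threshold=ic_threshold, col_min=col_min, col_range=col_range,
        assignment_rule=assignment_rule, seed=seed)


def assign_clusters(model: Level1Model, X: np.ndarray) -> np.ndarray:
    """Cluster index per row; ties go to the lowest-indexed cluster."""
    X = np.atleast_2d(X)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("feature dimension does not match the level-1 model")
    X = model.normalize(X)
    if model.assignment_rule == "centroid":
        return np.argmin(cdist(X, model.centroids), axis=1)
    d = cdist(X, model.member_x)                    # (m, n_train)
    mean_d = np.empty((X.shape[0], model.k))
    for c in range(model.k):
        cols = model.member_cluster == c
        mean_d[:, c] = d[:, cols].mean(axis=1) if cols.any() else np.inf
    return np.argmin(mean_d, axis=1)


def predict_level1(model: Level1Model, X: np.ndarray) -> np.ndarray:
    """Gate decision per row: "ic" or "nc"."""
    clusters = assign_clusters(model, X)
    return np.where(model.cluster_is_ic[clusters], IC, NC)


# ---------------------------------------------------------------------------
# level 2


@dataclass
class Level2Model:
    """Standardised linear SVM over the imagery classes (one-vs-one votes)."""

    pipeline: Pipeline
    classes: tuple
    include_nc: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.atleast_2d(X))


def fit_level2(train2: FeatureMatrix, include_nc: bool = False,
               c: float = 1.0, kernel: str = "linear") -> Level2Model:
    """Fit the second-level SVM on the IC training set.

    ``include_nc=True`` trains the 5-class variant in which level 2 may also
    answer NC, recovering level-1 false positives.
    """
    wanted = IC_CLASSES + ((NC,) if include_nc else ())
    present = set(train2.labels)
    missing = [cl for cl in wanted if cl not in present]
    if missing:
        raise ValueError(f"missing training class(es): {missing}")
    keep = np.isin(train2.labels, wanted)
    pipe = Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(kernel=kernel, C=c,
                                 decision_function_shape="ovo"))])
    pipe.fit(train2.values[keep], train2.labels[keep])
    return Level2Model(pipeline=pipe, classes=tuple(wanted),
                       include_nc=include_nc)


@dataclass
class HierarchicalClassifier:
    """Reject-then-classify composition of the two levels.

    The two levels are trained on disjoint sets (TrainingSet1 for the gate,
    TrainingSet2 for the SVM); the classifier also carries the CSP model and
    feature mask so it can be applied to raw feature rows end to end.
    """

    level1: Level1Model
    level2: Level2Model
    mask: SelectionMask = None
    csp: object = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.array(predict_level1(self.level1, X), dtype=object)
        gate_ic = out == IC
        if gate_ic.any():
            out[gate_ic] = self.level2.predict(X[gate_ic])
        return out.astype(str)


# ---------------------------------------------------------------------------
# (K, IC-threshold) grid search


@dataclass
class GridResult:
    """Cross-validated accuracy/FPR per grid cell and the selected cell."""

    table: pd.DataFrame            # columns: K, ic_threshold, accuracy, fpr
    fpr_bound: float
    best: tuple = None             # (K, ic_threshold) or None if infeasible

    @property
    def feasible(self) -> bool:
        return self.best is not None

    def best_row(self) -> pd.Series:
        if self.best is None:
            raise ValueError("no feasible grid cell")
        t = self.table
        return t[(t.K == self.best[0])
                 & (t.ic_threshold == self.best[1])].iloc[0]


def grid_search(train1, k_grid=DEFAULT_K_GRID, t_grid=DEFAULT_T_GRID,
                n_runs: int = 5, n_folds: int = 10, fpr_bound: float = 0.10,
                seed: int = 0, assignment_rule: str = "average",
                n_init: int = 10) -> GridResult:
    """Estimate (K, IC-threshold) under the FPR bound by repeated CV.

    ``train1`` is a FeatureMatrix or a list of them (one per outer run, as
    produced by the run partition); each is evaluated with seeded stratified
    ``n_folds``-fold CV, ``n_runs`` times per matrix when a single matrix is
    given and once per matrix otherwise, and cell scores are averaged over
    all folds.  For one fitted clustering every threshold is evaluated by
    re-labelling, so the search cost scales with ``len(k_grid)`` only.

    The selected cell maximises mean accuracy among cells with mean FPR
    strictly below ``fpr_bound``; ties break toward lower FPR, then lower K,
    then lower threshold.  If no cell is feasible ``best`` is None and the
    table doubles as the feasibility report.
    """
    if not len(k_grid) or not len(t_grid):
        raise ValueError("empty parameter grid")
    mats = train1 if isinstance(train1, (list, tuple)) else [train1] * n_runs
    k_grid = list(k_grid)
    t_grid = [float(t) for t in t_grid]
    acc = np.zeros((len(k_grid), len(t_grid)))
    fp = np.zeros((len(k_grid), len(t_grid)))
    tn = np.zeros((len(k_grid), len(t_grid)))
    n_scored = np.zeros((len(k_grid), len(t_grid)))
    n_eval = np.zeros((len(k_grid), len(t_grid)))
    rng = np.random.default_rng(seed)
    for run, fm in enumerate(mats):
        y_bin = collapse_ic(fm.labels)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        for tr_idx, va_idx in skf.split(fm.values, fm.labels):
            tr = fm.rows(tr_idx)
            Xva, yva = fm.values[va_idx], y_bin[va_idx]
            n_nc = int((yva == NC).sum())
            for i, k in enumerate(k_grid):
                if k > len(tr_idx):
                    continue
                m1 = fit_level1(tr, k, ic_threshold=t_grid[0],
                                seed=int(rng.integers(2 ** 31 - 1)),
                                assignment_rule=assignment_rule,
                                n_init=n_init)
                clusters = assign_clusters(m1, Xva)
                for j, t in enumerate(t_grid):
                    lab = label_clusters(m1.member_cluster, m1.member_is_ic,
                                         k, t)
                    pred = np.where(lab[clusters], IC, NC)
                    acc[i, j] += (pred == yva).mean()
                    cell_fp = int(((yva == NC) & (pred == IC)).sum())
                    fp[i, j] += cell_fp
                    tn[i, j] += n_nc - cell_fp
                    n_scored[i, j] += 1
    rows = []
    for i, k in enumerate(k_grid):
        for j, t in enumerate(t_grid):
            if n_scored[i, j] == 0:
                rows.append((k, t, np.nan, np.nan))
                continue
            denom = fp[i, j] + tn[i, j]
            rows.append((k, t, 100.0 * acc[i, j] / n_scored[i, j],
                         100.0 * fp[i, j] / denom if denom else np.nan))
    table = pd.DataFrame(rows, columns=["K", "ic_threshold",
                                        "accuracy", "fpr"])
    skipped = int((n_scored == 0).any(axis=1).sum())
    if skipped:
        warnings.warn(f"{skipped} K value(s) exceeded the fold size and "
                      "were not evaluated")
    ok = table.dropna()
    ok = ok[ok.fpr < 100.0 * fpr_bound]
    best = None
    if len(ok):
        ok = ok.sort_values(["accuracy", "fpr", "K", "ic_threshold"],
                            ascending=[False, True, True, True])
        r = ok.iloc[0]
        best = (int(r.K), float(r.ic_threshold))
    return GridResult(table=table, fpr_bound=fpr_bound, best=best)
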