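"""Correlation-based feature selection (CFS) with best-first forward search.

CFS scores a feature subset S of size k by the merit

    M(S) = k * mean(|r_fc|) / sqrt(k + k (k - 1) * mean(|r_ff|))

where r_fc are feature-class correlations and r_ff pairwise feature-feature
correlations within S: subsets are good when their members predict the class
but do not duplicate one another.  The search starts from the empty set and
expands the best open subset by one feature at a time, stopping after a run
of non-improving expansions (Weka's best-first with a stall limit).

Two correlation measures are available: averaged one-vs-rest point-biserial
Pearson correlation (default) and discretized symmetrical uncertainty.
"""

from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix


@dataclass
class SelectionMask:
    """Kept feature columns plus the merit trajectory of the search."""

    kept: np.ndarray                  # sorted column indices
    merit_trace: list                 # [(subset size, merit), ...] best-so-far
    columns: list = None              # names of the kept columns
    source: str = "train"

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=int)

    def __len__(self):
        return len(self.kept)

    @property
    def merit(self) -> float:
        return self.merit_trace[-1][1] if self.merit_trace else 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"kept": self.kept.tolist(),
                       "columns": self.columns,
                       "merit_trace": self.merit_trace,
                       "source": self.source}, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionMask":
        with open(path) as f:
            d = json.load(f)
        return cls(kept=d["kept"], merit_trace=[tuple(t) for t
                                                in d["merit_trace"]],
                   columns=d.get("columns"), source=d.get("source", "train"))


def _pearson_correlations(X: np.ndarray, y: np.ndarray):
    """(|r_fc| averaged over one-vs-rest class indicators, |r_ff| matrix)."""
    n, d = X.shape
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    Z = Xs / sd_safe
    classes = np.unique(y)
    r_fc = np.zeros(d)
    for c in classes:
        ind = (y == c).astype(float)
        s = ind.std()
        if s == 0:
            continue
        r_fc += np.abs(Z.T @ ((ind - ind.mean()) / s)) / n
    r_fc /= len(classes)
    r_ff = np.abs(Z.T @ Z) / n
    np.fill_diagonal(r_ff, 1.0)
    r_fc[const] = 0.0
    r_ff[const] = 0.0
    r_ff[:, const] = 0.0
    return r_fc, r_ff, const


def _discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    codes = np.empty(X.shape, dtype=np.int32)
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], np.linspace(0, 1, n_bins + 1)))
        codes[:, j] = np.searchsorted(edges[1:-1], X[:, j], side="right")
    return codes


def _symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ab = a.astype(np.int64) * (b.max() + 1) + b
    def ent(v):
        _, cnt = np.unique(v, return_counts=True)
        p = cnt / cnt.sum()
        return -(p * np.log2(p)).sum()
    ha, hb, hab = ent(a), ent(b), ent(ab)
    denom = ha + hb
    return 0.0 if denom == 0 else 2.0 * (ha + hb - hab) / denom


def _su_correlations(X: np.ndarray, y: np.ndarray):
    codes = _discretize(X)
    _, ycodes = np.unique(y, return_inverse=True)
    d = X.shape[1]
    const = X.std(axis=0) == 0
    r_fc = np.array([_symmetrical_uncertainty(codes[:, j], ycodes)
                     for j in range(d)])
    r_ff = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            r_ff[i, j] = r_ff[j, i] = _symmetrical_uncertainty(codes[:, i],
                                                               codes[:, j])
    r_fc[const] = 0.0
    r_ff[const] = 0.0
    r_ff[:, const] = 0.0
    return r_fc, r_ff, const


def cfs_merit(subset, r_fc: np.ndarray, r_ff: np.ndarray) -> float:
    """CFS merit of an explicit subset (used by tests as a direct oracle)."""
    idx = np.asarray(sorted(subset), dtype=int)
    k = len(idx)
    if k == 0:
        return 0.0
    sum_fc = r_fc[idx].sum()
    sum_ff = r_ff[np.ix_(idx, idx)].sum() - k   # off-diagonal, both triangles
    return sum_fc / np.sqrt(k + sum_ff)


def cfs_select(train: FeatureMatrix, stall_limit: int = 5,
               measure: str = "pearson") -> SelectionMask:
    """Best-first forward CFS on a training feature matrix.

    Ties in merit are broken toward the subset generated first, and
    successors are generated in ascending column order, so the result is
    deterministic.  Constant columns are excluded with a warning.
    """
    X, y = train.values, train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least 2 classes")
    if measure == "pearson":
        r_fc, r_ff, const = _pearson_correlations(X, y)
    elif measure == "su":
        r_fc, r_ff, const = _su_correlations(X, y)
    else:
        raise ValueError(f"unknown correlation measure {measure!r}")
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature column(s) "
                      "excluded from selection")
    candidates = np.nonzero(~const)[0]

    # merit is computed incrementally: adding feature f to S changes the
    # correlation sums by r_fc[f] and 2 * sum(r_ff[f, S])
    empty = frozenset()
    best_set, best_merit = empty, 0.0
    trace = [(0, 0.0)]
    heap = [(0.0, 0, empty)]          # (-merit, tiebreak counter, subset)
    sums = {empty: (0.0, 0.0)}        # subset -> (sum_fc, sum_ff off-diag)
    visited = {empty}
    counter = 0
    stall = 0
    while heap and stall < stall_limit:
        _, _, s = heapq.heappop(heap)
        sum_fc, sum_ff = sums[s]
        improved = False
        s_idx = np.fromiter(s, dtype=int) if s else np.empty(0, dtype=int)
        for f in candidates:
            if f in s:
                continue
            t = s | {int(f)}
            if t in visited:
                continue
            visited.add(t)
            t_fc = sum_fc + r_fc[f]
            t_ff = sum_ff + 2.0 * (r_ff[f, s_idx].sum() if len(s_idx) else 0.0)
            k = len(t)
            merit = t_fc / np.sqrt(k + t_ff)
            sums[t] = (t_fc, t_ff)
            counter += 1
            heapq.heappush(heap, (-merit, counter, t))
            if merit > best_merit + 1e-12:
                best_merit, best_set = merit, t
                trace.append((k, merit))
                improved = True
        stall = 0 if improved else stall + 1
    if not best_set:
        raise ValueError("feature selection found no informative feature")
    kept = np.array(sorted(best_set), dtype=int)
    return SelectionMask(kept=kept, merit_trace=trace,
                         columns=[train.columns[i] for i in kept])


def apply_mask(mask: SelectionMask, matrix: FeatureMatrix) -> FeatureMatrix:
    """Column-subset a matrix with a fitted mask (order preserved)."""
    if len(mask) == 0:
        raise ValueError("refusing to apply an empty feature mask")
    if mask.kept.max() >= matrix.n_features:
        raise IndexError("mask index out of range for this matrix")
    return matrix.select_columns(mask.kept)
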