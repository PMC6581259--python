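"""End-to-end protocol runs: features per partition, hierarchy, baselines.

Each protocol run repeats the whole chain on its own random partition:
CSP and the feature mask are fitted on that run's training epochs only, so
nothing from a test set ever informs preprocessing, selection or training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .evaluation import (EvaluationReport, accuracy, confusion, fpr,
                         make_classifier)
from .features import FeatureMatrix, assemble_matrix
from .hierarchy import (IC, HierarchicalClassifier, collapse_ic, fit_level1,
                        fit_level2, grid_search, predict_level1)
from .io import (ALL_CLASSES, IC_CLASSES, NC, EpochSet, RawSession,
                 extract_epochs, partition_runs)
from .preprocessing import fit_csp_ovr, prefilter
from .selection import apply_mask, cfs_select

logger = logging.getLogger(__name__)


@dataclass
class RunFeatures:
    """Masked feature matrices of one partition plus the fitted models."""

    train1: FeatureMatrix
    train2: FeatureMatrix
    test: FeatureMatrix
    csp: object
    mask: object


def session_epochs(session: RawSession,
                   config: PipelineConfig = None) -> EpochSet:
    """Prefilter a session and cut its IC/NC epochs per the trial template."""
    config = config or PipelineConfig()
    filtered = prefilter(session, band=config.broadband,
                         order=config.broadband_order, notch=config.notch,
                         notch_q=config.notch_q)
    return extract_epochs(filtered, ic_window=config.ic_window,
                          nc_window=config.nc_window,
                          nc_fraction=config.nc_fraction, seed=config.seed)


def prepare_run_features(split, config: PipelineConfig) -> RunFeatures:
    """Fit CSP + CFS on a run's training epochs and featurise all three sets."""
    train_epochs = split.training_epochs()
    csp = fit_csp_ovr(train_epochs, n_keep=config.n_keep,
                      shrinkage=config.csp_shrinkage)
    fm1 = assemble_matrix(csp, split.training_set_1, bands=config.bands,
                          band_order=config.band_order)
    fm2 = assemble_matrix(csp, split.training_set_2, bands=config.bands,
                          band_order=config.band_order)
    fmt = assemble_matrix(csp, split.test_set, bands=config.bands,
                          band_order=config.band_order)
    mask = cfs_select(FeatureMatrix.concat([fm1, fm2]),
                      stall_limit=config.cfs_stall,
                      measure=config.cfs_measure)
    return RunFeatures(train1=apply_mask(mask, fm1),
                       train2=apply_mask(mask, fm2),
                       test=apply_mask(mask, fmt), csp=csp, mask=mask)


def _five_class_train(run: RunFeatures) -> FeatureMatrix:
    # the 5-class variant needs NC training rows; TrainingSet2 is IC-only,
    # so the NC rows of TrainingSet1 are added to it
    nc_rows = run.train1.rows(run.train1.labels == NC)
    return FeatureMatrix.concat([run.train2, nc_rows])


def evaluate_hierarchical(epochs: EpochSet, config: PipelineConfig = None,
                          seed: int = None, select_grid: bool = False,
                          subject_id: str = "") -> EvaluationReport:
    """Run the full 5-run protocol for the two-level hierarchical system.

    With ``select_grid=True`` the (K, IC-threshold) pair is first estimated
    from the runs' TrainingSet1 matrices by the FPR-constrained grid search
    (cross-validated within each run), then applied to every run; otherwise
    ``config.k`` / ``config.ic_threshold`` are used directly.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    splits = partition_runs(epochs, n_runs=config.n_runs, seed=seed)
    runs = [prepare_run_features(s, config) for s in splits]

    grid = None
    k, t = config.k, config.ic_threshold
    if select_grid:
        grid = grid_search([r.train1 for r in runs], k_grid=config.k_grid,
                           t_grid=config.t_grid, n_folds=config.n_folds,
                           fpr_bound=config.fpr_bound,
                           seed=int(rng.integers(2 ** 31 - 1)),
                           assignment_rule=config.assignment_rule,
                           n_init=config.kmeans_restarts)
        if grid.feasible:
            k, t = grid.best
        else:
            logger.warning("grid search found no feasible cell; falling "
                           "back to config K=%d, t=%.2f", k, t)

    include_nc = config.variant == "five"
    rows, cms1, cms2, cms5 = [], [], [], []
    for i_run, run in enumerate(runs):
        seed_run = int(rng.integers(2 ** 31 - 1))
        level1 = fit_level1(run.train1, k, ic_threshold=t, seed=seed_run,
                            assignment_rule=config.assignment_rule,
                            n_init=config.kmeans_restarts)
        train2 = _five_class_train(run) if include_nc else run.train2
        level2 = fit_level2(train2, include_nc=include_nc, c=config.svm_c,
                            kernel=config.svm_kernel)
        clf = HierarchicalClassifier(level1, level2, mask=run.mask,
                                     csp=run.csp)
        truth = run.test.labels
        pred = clf.predict(run.test.values)

        cm5 = confusion(truth, pred, ALL_CLASSES)
        cm1 = confusion(collapse_ic(truth), collapse_ic(pred), (IC, NC))
        # level-2 view: true-IC instances that passed the gate
        gated = (collapse_ic(truth) == IC) & (collapse_ic(pred) == IC)
        cm2 = (confusion(truth[gated], pred[gated], IC_CLASSES) if gated.any()
               else np.zeros((len(IC_CLASSES),) * 2, dtype=int))
        cms1.append(cm1)
        cms2.append(cm2)
        cms5.append(cm5)
        rows.append({
            "run": i_run,
            "accuracy": accuracy(cm5),
            "fpr": fpr(cm5, ALL_CLASSES),
            "level1_accuracy": accuracy(cm1),
            "level2_accuracy": accuracy(cm2) if cm2.sum() else np.nan,
            "n_test": int(cm5.sum()),
            "n_features": len(run.mask),
        })
    per_run = pd.DataFrame(rows)
    return EvaluationReport(
        per_run=per_run,
        level1_confusion=np.mean(cms1, axis=0),
        level2_confusion=np.mean(cms2, axis=0),
        overall_confusion=np.mean(cms5, axis=0),
        config=config.to_dict(), chosen_k=k, chosen_threshold=t, grid=grid,
        n_selected_features=float(per_run["n_features"].mean()),
        subject_id=subject_id)


# ---------------------------------------------------------------------------
# supervised baselines


def _baseline_report(rows, cms, config, subject_id, n_feats) -> EvaluationReport:
    per_run = pd.DataFrame(rows)
    zero2 = np.zeros((len(IC_CLASSES), len(IC_CLASSES)))
    return EvaluationReport(
        per_run=per_run,
        level1_confusion=np.mean([c[0] for c in cms], axis=0),
        level2_confusion=(np.mean([c[1] for c in cms], axis=0)
                          if cms[0][1] is not None else zero2),
        overall_confusion=np.mean([c[2] for c in cms], axis=0),
        config=config.to_dict(), chosen_k=0, chosen_threshold=np.nan,
        n_selected_features=n_feats, subject_id=subject_id)


def one_level_baseline(epochs: EpochSet, classifier: str = "svm",
                       config: PipelineConfig = None, seed: int = None,
                       subject_id: str = "") -> EvaluationReport:
    """Single supervised classifier over all five classes.

    The training set balances the five classes: all IC training rows (both
    training sets) plus an equal-sized seeded subsample of NC rows.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    splits = partition_runs(epochs, n_runs=config.n_runs, seed=seed)
    rows, cms = [], []
    n_feats = []
    for i, split in enumerate(splits):
        run = prepare_run_features(split, config)
        n_feats.append(len(run.mask))
        train = FeatureMatrix.concat([run.train1, run.train2])
        ic_rows = train.labels != NC
        per_class = int(ic_rows.sum()) // len(IC_CLASSES)
        nc_idx = np.nonzero(~ic_rows)[0]
        keep = np.concatenate([np.nonzero(ic_rows)[0],
                               rng.choice(nc_idx,
                                          size=min(per_class, len(nc_idx)),
                                          replace=False)])
        train = train.rows(np.sort(keep))
        clf = make_classifier(classifier, seed=int(rng.integers(2 ** 31 - 1)),
                              svm_c=config.svm_c)
        clf.fit(train.values, train.labels)
        truth, pred = run.test.labels, clf.predict(run.test.values)
        cm5 = confusion(truth, pred, ALL_CLASSES)
        cm1 = confusion(collapse_ic(truth), collapse_ic(pred), (IC, NC))
        cms.append((cm1, None, cm5))
        rows.append({"run": i, "accuracy": accuracy(cm5),
                     "fpr": fpr(cm5, ALL_CLASSES),
                     "level1_accuracy": accuracy(cm1),
                     "level2_accuracy": np.nan, "n_test": int(cm5.sum()),
                     "n_features": len(run.mask)})
    return _baseline_report(rows, cms, config, subject_id,
                            float(np.mean(n_feats)))


def two_level_supervised_baseline(epochs: EpochSet, level1: str = "knn",
                                  level2: str = "svm",
                                  config: PipelineConfig = None,
                                  seed: int = None,
                                  subject_id: str = "") -> EvaluationReport:
    """Supervised IC/NC gate (TrainingSet1) + 4-class classifier (Set2)."""
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    splits = partition_runs(epochs, n_runs=config.n_runs, seed=seed)
    rows, cms = [], []
    n_feats = []
    for i, split in enumerate(splits):
        run = prepare_run_features(split, config)
        n_feats.append(len(run.mask))
        gate = make_classifier(level1, seed=int(rng.integers(2 ** 31 - 1)),
                               svm_c=config.svm_c)
        gate.fit(run.train1.values, collapse_ic(run.train1.labels))
        clf2 = make_classifier(level2, seed=int(rng.integers(2 ** 31 - 1)),
                               svm_c=config.svm_c)
        clf2.fit(run.train2.values, run.train2.labels)
        truth = run.test.labels
        pred = np.array(gate.predict(run.test.values), dtype=object)
        m = pred == IC
        if m.any():
            pred[m] = clf2.predict(run.test.values[m])
        pred = pred.astype(str)
        cm5 = confusion(truth, pred, ALL_CLASSES)
        cm1 = confusion(collapse_ic(truth), collapse_ic(pred), (IC, NC))
        gated = (collapse_ic(truth) == IC) & (collapse_ic(pred) == IC)
        cm2 = (confusion(truth[gated], pred[gated], IC_CLASSES) if gated.any()
               else np.zeros((len(IC_CLASSES),) * 2, dtype=int))
        cms.append((cm1, cm2, cm5))
        rows.append({"run": i, "accuracy": accuracy(cm5),
                     "fpr": fpr(cm5, ALL_CLASSES),
                     "level1_accuracy": accuracy(cm1),
                     "level2_accuracy": accuracy(cm2) if cm2.sum()
                     else np.nan,
                     "n_test": int(cm5.sum()), "n_features": len(run.mask)})
    return _baseline_report(rows, cms, config, subject_id,
                            float(np.mean(n_feats)))
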