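import numpy as np
import pytest

from bcihier.features import FeatureMatrix
from bcihier.hierarchy import (IC, DEFAULT_K_GRID, DEFAULT_T_GRID,
                               HierarchicalClassifier, Level1Model,
                               assign_clusters, collapse_ic, fit_level1,
                               fit_level2, grid_search, label_clusters,
                               predict_level1)
from bcihier.io import IC_CLASSES, NC


def fm(X, y):
    X = np.asarray(X, float)
    return FeatureMatrix(X, [f"f{i}" for i in range(X.shape[1])],
                         np.asarray(y))


def blobs(rng, n_per=40, sep=8.0, d=4, noise=1.0):
    """Two well separated Gaussian blobs: one pure IC, one pure NC."""
    ic = rng.standard_normal((n_per, d)) * noise
    nc = rng.standard_normal((n_per, d)) * noise + sep
    X = np.vstack([ic, nc])
    y = np.array(["left"] * n_per + [NC] * n_per)
    return fm(X, y)


class TestThresholdLabelling:
    def test_inclusive_rule(self):
        assign = np.zeros(10, int)
        is_ic = np.array([True] * 8 + [False] * 2)
        assert label_clusters(assign, is_ic, 1, 0.8)[0]        # 0.8 >= 0.8
        is_ic = np.array([True] * 7 + [False] * 3)
        assert not label_clusters(assign, is_ic, 1, 0.8)[0]    # 0.7 < 0.8

    def test_monotone_in_threshold(self, rng):
        """For a fixed clustering, raising the IC threshold can only turn
        IC clusters into NC ones, so FPR and the IC-cluster count are
        non-increasing."""
        X = rng.standard_normal((120, 5))
        y = rng.choice(["left", "right", NC], size=120)
        model = fit_level1(fm(X, y), k=10, seed=0)
        n_ic, fprs = [], []
        truth = collapse_ic(y)
        for t in np.linspace(0.05, 1.0, 20):
            m = model.relabel(t)
            n_ic.append(int(m.cluster_is_ic.sum()))
            pred = np.where(m.cluster_is_ic[m.member_cluster], IC, NC)
            nc_rows = truth == NC
            fprs.append((pred[nc_rows] == IC).mean())
        assert all(a >= b for a, b in zip(n_ic, n_ic[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(fprs, fprs[1:]))


class TestLevel1:
    def test_separable_blobs(self, rng):
        train = blobs(rng)
        model = fit_level1(train, k=2, ic_threshold=0.8, seed=0)
        assert sorted(model.cluster_is_ic.tolist()) == [False, True]
        pred = predict_level1(model, train.values)
        assert (pred == collapse_ic(train.labels)).all()   # training FPR 0

    def test_member_recovers_own_cluster_label(self, rng):
        train = blobs(rng, n_per=10)
        model = fit_level1(train, k=2, seed=1)
        for i in (0, 15):
            lab = predict_level1(model, train.values[i][None, :])[0]
            want = IC if model.cluster_is_ic[model.member_cluster[i]] else NC
            assert lab == want

    def test_midpoint_tie_goes_to_lower_cluster(self):
        members = np.array([[0.0, 0.0], [2.0, 0.0]])
        model = Level1Model(
            k=2, centroids=members.copy(), member_x=members,
            member_cluster=np.array([0, 1]),
            member_is_ic=np.array([True, False]),
            cluster_is_ic=np.array([True, False]), ic_threshold=0.8,
            col_min=np.zeros(2), col_range=np.ones(2))
        assert assign_clusters(model, np.array([[1.0, 0.0]]))[0] == 0
        assert predict_level1(model, np.array([[1.0, 0.0]]))[0] == IC

    def test_average_and_centroid_rules_agree_when_separable(self, rng):
        train = blobs(rng, n_per=60)
        test = blobs(rng, n_per=60)
        avg = fit_level1(train, k=2, seed=0, assignment_rule="average")
        cen = avg
        a = assign_clusters(avg, test.values)
        cen = Level1Model(**{**avg.__dict__, "assignment_rule": "centroid"})
        c = assign_clusters(cen, test.values)
        assert (a == c).mean() > 0.99

    def test_k_exceeding_rows(self, rng):
        with pytest.raises(ValueError, match="K"):
            fit_level1(blobs(rng, n_per=3), k=10)

    def test_dimension_mismatch(self, rng):
        model = fit_level1(blobs(rng), k=2)
        with pytest.raises(ValueError, match="dimension"):
            predict_level1(model, np.zeros((1, 9)))

    def test_seed_determinism(self, rng):
        train = blobs(rng, noise=4.0, sep=3.0)
        a = fit_level1(train, k=5, seed=42)
        b = fit_level1(train, k=5, seed=42)
        np.testing.assert_allclose(a.centroids, b.centroids)
        np.testing.assert_array_equal(a.member_cluster, b.member_cluster)


def four_class_data(rng, n_per=12, d=8, sep=10.0, noise=1.0):
    X, y = [], []
    for i, cls in enumerate(IC_CLASSES):
        mu = np.zeros(d)
        mu[i] = sep
        X.append(rng.standard_normal((n_per, d)) * noise + mu)
        y += [cls] * n_per
    return fm(np.vstack(X), np.array(y))


class TestLevel2:
    def test_separable_training_accuracy(self, rng):
        train = four_class_data(rng)
        model = fit_level2(train)
        assert (model.predict(train.values) == train.labels).all()

    def test_five_class_variant_alphabet(self, rng):
        train = four_class_data(rng)
        nc = fm(rng.standard_normal((12, 8)) - 10.0, np.array([NC] * 12))
        both = FeatureMatrix.concat([train, nc])
        model = fit_level2(both, include_nc=True)
        assert set(model.classes) == set(IC_CLASSES) | {NC}
        assert (model.predict(nc.values) == NC).all()

    def test_missing_class_rejected(self, rng):
        train = four_class_data(rng)
        sub = train.rows(train.labels != "tongue")
        with pytest.raises(ValueError, match="missing"):
            fit_level2(sub)

    def test_label_permutation_equivariance(self, rng):
        train = four_class_data(rng)
        test = four_class_data(rng)
        swap = {"left": "right", "right": "left"}
        permuted = fm(train.values,
                      np.array([swap.get(l, l) for l in train.labels]))
        p1 = fit_level2(train).predict(test.values)
        p2 = fit_level2(permuted).predict(test.values)
        assert (p2 == np.array([swap.get(l, l) for l in p1])).all()


class TestHierarchicalClassifier:
    def build(self, rng, all_nc=False):
        level1 = fit_level1(blobs(rng), k=2, ic_threshold=0.8, seed=0)
        if all_nc:
            level1.cluster_is_ic = np.zeros_like(level1.cluster_is_ic)
        level2 = fit_level2(four_class_data(rng, d=4))
        return HierarchicalClassifier(level1, level2)

    def test_gate_semantics(self, rng):
        clf = self.build(rng, all_nc=True)   # every cluster labelled NC
        out = clf.predict(rng.standard_normal((7, 4)))
        assert (out == NC).all()

    def test_gate_consistency(self, rng):
        """4-class variant: whatever level 1 rejects stays NC, whatever it
        accepts gets an IC class."""
        clf = self.build(rng)
        X = np.vstack([rng.standard_normal((30, 4)),
                       rng.standard_normal((30, 4)) + 8.0])
        gate = predict_level1(clf.level1, X)
        out = clf.predict(X)
        assert ((gate == NC) == (out == NC)).all()
        assert set(out[gate == IC]) <= set(IC_CLASSES)


class TestGridSearch:
    def test_feasible_best_on_separable_data(self, rng):
        train = blobs(rng, n_per=50)
        res = grid_search(train, k_grid=(2, 4), t_grid=(0.6, 0.8),
                          n_runs=2, n_folds=5, seed=0)
        assert res.feasible
        row = res.best_row()
        assert row.fpr < 10.0
        assert row.accuracy > 95.0
        assert len(res.table) == 4

    def test_infeasible_grid_reports_no_best(self, rng):
        X = rng.standard_normal((80, 3))        # labels independent of X
        y = np.array((["left"] * 80))
        y[::2] = NC
        res = grid_search(fm(X, y), k_grid=(2,), t_grid=(0.01,),
                          n_runs=1, n_folds=4, fpr_bound=0.02, seed=0)
        assert not res.feasible
        assert np.isfinite(res.table.accuracy).all()
        with pytest.raises(ValueError):
            res.best_row()

    def test_constraint_dominates_accuracy(self, rng):
        """A cell violating the FPR bound is never selected, even if it has
        the highest accuracy."""
        train = blobs(rng, n_per=50, sep=2.5, noise=1.5)  # overlapping
        res = grid_search(train, k_grid=(2, 6), t_grid=(0.3, 0.6, 0.9),
                          n_runs=2, n_folds=5, fpr_bound=0.10, seed=1)
        ok = res.table.dropna()
        if res.feasible:
            best_acc_any = ok.accuracy.max()
            row = res.best_row()
            assert row.fpr < 10.0
            infeasible = ok[ok.fpr >= 10.0]
            if len(infeasible) and infeasible.accuracy.max() > row.accuracy:
                assert row.accuracy < best_acc_any

    def test_oversized_k_skipped_with_warning(self, rng):
        train = blobs(rng, n_per=10)
        with pytest.warns(UserWarning, match="fold size"):
            res = grid_search(train, k_grid=(2, 500), t_grid=(0.8,),
                              n_runs=1, n_folds=2, seed=0)
        assert res.table[res.table.K == 500].accuracy.isna().all()

    def test_determinism(self, rng):
        train = blobs(rng, sep=3.0, noise=2.0)
        a = grid_search(train, k_grid=(2, 3), t_grid=(0.5, 0.8),
                        n_runs=2, n_folds=4, seed=9)
        b = grid_search(train, k_grid=(2, 3), t_grid=(0.5, 0.8),
                        n_runs=2, n_folds=4, seed=9)
        assert a.table.equals(b.table) and a.best == b.best

    def test_default_grids(self):
        assert DEFAULT_K_GRID == (5, 10, 15, 20, 25, 30, 35, 40, 45, 50,
                                  55, 60)
        assert DEFAULT_T_GRID[0] == 0.50 and DEFAULT_T_GRID[-1] == 0.95
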