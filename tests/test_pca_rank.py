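"""Eigenvalue-weighted ranking: oracle equivalence and invariants."""

import math

import numpy as np
import pytest
import scipy.linalg
from sklearn.base import clone

from icpca import (FeatureMatrix, FeatureSet, InputError,
                   InternalCoordinatePCA, NumericalError, compare,
                   rank_matrix)
from icpca.pca_rank import pca, preprocess, score_and_rank, select_pcs


def brute_force_scores(X, variance_threshold=0.90):
    """Independent oracle: explicit covariance loops + scipy.linalg.eig.

    Shares no code path with the implementation (element-wise covariance
    accumulation, general eigensolver, explicit cumulative-sum loop).
    """
    n, p = X.shape
    means = [sum(X[:, j]) / n for j in range(p)]
    cov = np.empty((p, p))
    for a in range(p):
        for b in range(p):
            cov[a, b] = sum((X[f, a] - means[a]) * (X[f, b] - means[b])
                            for f in range(n)) / (n - 1)
    evals, evecs = scipy.linalg.eig(cov)
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    k, acc = 0, 0.0
    while acc / total < 0.90 - 1e-12:
        acc += evals[k]
        k += 1
    return np.array([sum(evals[j] * abs(evecs[i, j]) for j in range(k))
                     for i in range(p)])


def bond_matrix(values):
    values = np.asarray(values, dtype=float)
    p = values.shape[1]
    fs = FeatureSet("bond", [(2 * i, 2 * i + 1) for i in range(p)])
    return FeatureMatrix(values, fs)


class TestPreprocess:
    def test_dihedral_branch_cut_rewrap(self):
        fs = FeatureSet("dihedral", [(0, 1, 2, 3)])
        fm = FeatureMatrix(np.array([[179.0], [-179.0]]), fs)
        centered, _ = preprocess(fm)
        np.testing.assert_allclose(sorted(centered[:, 0]), [-1.0, 1.0],
                                   atol=1e-9)
        assert np.var(centered[:, 0], ddof=1) == pytest.approx(2.0)

    def test_centered_column_unchanged(self):
        fm = bond_matrix([[1.0, -0.5], [-1.0, 0.5]])
        centered, _ = preprocess(fm)
        np.testing.assert_allclose(centered, fm.values, atol=1e-12)

    def test_constant_column_becomes_zero(self):
        fm = bond_matrix([[1.53, 2.0], [1.53, 3.0]])
        centered, _ = preprocess(fm)
        np.testing.assert_allclose(centered[:, 0], 0.0, atol=1e-12)

    def test_masked_cells_imputed_and_counted(self):
        fs = FeatureSet("dihedral", [(0, 1, 2, 3)])
        vals = np.array([[10.0], [np.nan], [20.0]])
        mask = np.isnan(vals)
        fm = FeatureMatrix(vals, fs, mask)
        centered, info = preprocess(fm)
        assert info["imputed_cells"] == 1
        assert np.isfinite(centered).all()

    def test_fully_masked_column_errors_with_feature_name(self):
        fs = FeatureSet("dihedral", [(0, 1, 2, 3)])
        vals = np.full((3, 1), np.nan)
        with pytest.raises(NumericalError, match="1-2-3-4"):
            preprocess(FeatureMatrix(vals, fs, np.isnan(vals)))

    def test_single_frame_rejected(self):
        with pytest.raises(InputError):
            preprocess(bond_matrix([[1.0, 2.0]]))


class TestPCA:
    def test_uncorrelated_columns_recover_variances(self, rng):
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std(ddof=1)
        y = rng.normal(size=500)
        y -= y.dot(x) / x.dot(x) * x          # orthogonalize exactly
        y = (y - y.mean()) / y.std(ddof=1)
        X = np.column_stack([2.0 * x, 1.0 * y])
        evals, _ = pca(X - X.mean(axis=0))
        np.testing.assert_allclose(evals, [4.0, 1.0], rtol=1e-8)

    def test_duplicated_column_gives_zero_eigenvalue(self, rng):
        col = rng.normal(size=50)
        X = np.column_stack([col, col])
        evals, _ = pca(X - X.mean(axis=0))
        assert evals[1] == pytest.approx(0.0, abs=1e-10)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(40, 6))
        centered = X - X.mean(axis=0)
        evals, evecs = pca(centered)
        cov = centered.T @ centered / (centered.shape[0] - 1)
        np.testing.assert_allclose(evecs @ np.diag(evals) @ evecs.T, cov,
                                   atol=1e-8)

    def test_eigenvalue_sum_equals_trace(self, rng):
        for _ in range(5):
            X = rng.normal(size=(30, 8)) * rng.uniform(0.1, 10, size=8)
            centered = X - X.mean(axis=0)
            evals, evecs = pca(centered)
            trace = np.trace(centered.T @ centered / 29)
            assert evals.sum() == pytest.approx(trace, rel=1e-8)
            np.testing.assert_allclose(evecs.T @ evecs, np.eye(8), atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(25, 4))
        _, v1 = pca(X - X.mean(axis=0))
        _, v2 = pca(X - X.mean(axis=0))
        np.testing.assert_array_equal(v1, v2)
        dominant = np.argmax(np.abs(v1), axis=0)
        assert np.all(v1[dominant, np.arange(4)] > 0)


class TestSelectPCs:
    @pytest.mark.parametrize("evals,expected", [
        ((8.0, 1.0, 1.0), 2),
        ((9.5, 0.5), 1),
        (tuple([1.0] * 10), 9),
    ])
    def test_cumulative_threshold(self, evals, expected):
        assert len(select_pcs(np.array(evals))) == expected

    def test_all_zero_errors(self):
        with pytest.raises(NumericalError):
            select_pcs(np.zeros(3))

    def test_threshold_configurable(self):
        assert len(select_pcs(np.array([8.0, 1.0, 1.0]), threshold=0.5)) == 1


class TestScoreAndRank:
    def test_worked_example_single_pc(self):
        evals = np.array([5.0])
        loadings = np.array([[0.8], [0.6]])
        r = score_and_rank(evals, loadings, np.array([0]))
        np.testing.assert_allclose(r.scores, [4.0, 3.0])
        assert list(r.order) == [0, 1]

    def test_top_set_size_is_ceil(self):
        evals = np.array([1.0])
        loadings = np.ones((77, 1)) / math.sqrt(77)
        r = score_and_rank(evals, loadings, np.array([0]), fraction=0.10)
        assert len(r.top_features) == 8

    def test_ties_break_by_ascending_index(self):
        evals = np.array([1.0])
        loadings = np.full((5, 1), 1.0 / math.sqrt(5))
        r = score_and_rank(evals, loadings, np.array([0]), fraction=0.4)
        assert list(r.top_features) == [0, 1]

    def test_invalid_fraction(self):
        with pytest.raises(InputError):
            score_and_rank(np.array([1.0]), np.ones((2, 1)), np.array([0]),
                           fraction=0.0)

    def test_sign_convention_invariance(self, rng):
        X = rng.normal(size=(30, 5)) * [5, 1, 1, 1, 1]
        centered = X - X.mean(axis=0)
        evals, evecs = pca(centered)
        sel = select_pcs(evals)
        flipped = evecs * np.where(rng.random(5) > 0.5, -1.0, 1.0)
        s1 = score_and_rank(evals, evecs, sel).scores
        s2 = score_and_rank(evals, flipped, sel).scores
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 7)) * rng.uniform(0.5, 5, size=7)
        perm = rng.permutation(7)
        s = rank_matrix(bond_matrix(X)).scores
        s_perm = rank_matrix(bond_matrix(X[:, perm])).scores
        np.testing.assert_allclose(s_perm, s[perm], rtol=1e-10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("p", [2, 3, 4, 5, 6])
    def test_scores_match_brute_force(self, rng, p):
        X = rng.normal(size=(40, p)) * rng.uniform(0.2, 8.0, size=p)
        expected = brute_force_scores(X)
        got = rank_matrix(bond_matrix(X)).scores
        np.testing.assert_allclose(got, expected, rtol=1e-8, atol=1e-12)


class TestCompare:
    def _ranking_with_top(self, top, n=10, name=""):
        scores = np.zeros(n)
        scores[list(top)] = np.arange(len(top), 0, -1)
        evals = np.array([1.0])
        loadings = np.zeros((n, 1))
        loadings[:, 0] = scores
        r = score_and_rank(evals, loadings, np.array([0]),
                           fraction=len(top) / n, name=name)
        assert r.top_set == set(top)
        return r

    def test_shared_feature_multiplicity(self):
        a = self._ranking_with_top({0, 1}, name="a")
        b = self._ranking_with_top({1, 5}, name="b")
        rep = compare([a, b])
        assert rep.membership.loc[rep.membership.index[1], "multiplicity"] == 2
        assert rep.multiplicity_counts == {1: 2, 2: 1}

    def test_identical_rankings_all_multiplicity_2(self):
        a = self._ranking_with_top({2, 3}, name="a")
        b = self._ranking_with_top({2, 3}, name="b")
        rep = compare([a, b])
        assert rep.multiplicity_counts == {2: 2}

    def test_mismatched_feature_sets_error(self):
        a = self._ranking_with_top({0}, n=5)
        b = self._ranking_with_top({0}, n=6)
        with pytest.raises(InputError):
            compare([a, b])

    def test_random_overlap_matches_hypergeometric_null(self):
        """Mean top-set overlap of two independent rankings of 259
        features (26 each) agrees with t^2/n within Monte-Carlo error."""
        n, reps = 259, 200
        t = math.ceil(0.1 * n)
        rng = np.random.default_rng(42)
        overlaps = []
        for _ in range(reps):
            X1 = rng.normal(size=(30, n))
            X2 = rng.normal(size=(30, n))
            r1 = rank_matrix(bond_matrix(X1), name="a")
            r2 = rank_matrix(bond_matrix(X2), name="b")
            overlaps.append(len(r1.top_set & r2.top_set))
        expected = t * t / n
        var = t * (t / n) * ((n - t) / n) * ((n - t) / (n - 1))
        sem = math.sqrt(var / reps)
        assert abs(np.mean(overlaps) - expected) < 5 * sem


class TestEstimator:
    def test_fit_attributes_and_recovery(self, rng):
        X = rng.normal(size=(250, 20))
        X[:, 4] *= 30.0
        est = InternalCoordinatePCA().fit(X)
        assert est.eigenvalues_.shape == (20,)
        assert est.loadings_.shape == (20, 20)
        assert 4 in set(est.top_features_)
        assert est.scores_.shape == (20,)

    def test_get_set_params_and_clone(self):
        est = InternalCoordinatePCA(variance_threshold=0.8, top_fraction=0.2)
        params = est.get_params()
        assert params["variance_threshold"] == 0.8
        c = clone(est)
        assert c.get_params() == params

    def test_transform_projects_onto_selected_pcs(self, rng):
        X = rng.normal(size=(100, 6)) * [10, 5, 1, 1, 1, 1]
        est = InternalCoordinatePCA().fit(X)
        Z = est.fit_transform(X)
        assert Z.shape == (100, len(est.selected_pcs_))
        np.testing.assert_allclose(Z.var(axis=0, ddof=1),
                                   est.eigenvalues_[est.selected_pcs_],
                                   rtol=1e-8)

    def test_correlation_option_changes_ranking_basis(self, rng):
        X = rng.normal(size=(200, 3)) * [100.0, 1.0, 1.0]
        cov_est = InternalCoordinatePCA().fit(X)
        cor_est = InternalCoordinatePCA(scale=True).fit(X)
        assert cov_est.scores_[0] > 10 * cov_est.scores_[1]
        # standardized columns carry comparable score mass
        assert cor_est.scores_.max() < 3 * cor_est.scores_.min()

    def test_sklearn_pipeline_compatible(self, rng):
        from sklearn.pipeline import Pipeline
        X = rng.normal(size=(50, 4))
        pipe = Pipeline([("pca", InternalCoordinatePCA(variance_threshold=0.99))])
        Z = pipe.fit_transform(X)
        assert Z.ndim == 2
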