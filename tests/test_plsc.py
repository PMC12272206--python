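"""PLSC fit, preprocessing and the family-aware resampling suite."""

import numpy as np
import pytest

from dfcstates import (
    bootstrap_ratios,
    cross_validate,
    permutation_test,
    plsc_fit,
    residualize_and_standardize,
    simulate_linked_matrices,
    splithalf_reproducibility,
    variance_explained,
)
from dfcstates.plsc import (
    cross_block_matrix,
    projected_singular_values,
    residualize_lenient,
)


class TestPreprocessing:
    def test_hand_ols_residuals(self):
        # column (2,4,6,9) on confound (1,2,3,4): slope 2.3, intercept -0.5,
        # residuals (0.2, -0.1, -0.4, 0.3), SD (ddof=1) = sqrt(0.1)
        M = np.array([[2.0], [4.0], [6.0], [9.0]])
        conf = np.array([1.0, 2.0, 3.0, 4.0])
        Z, params = residualize_and_standardize(M, conf)
        sd = np.sqrt(0.1)
        expected = np.array([0.2, -0.1, -0.4, 0.3]) / sd
        assert np.allclose(Z[:, 0], expected)
        assert np.allclose(params.beta[:, 0], [-0.5, 2.3])

    def test_column_orthogonal_to_confound_just_zscored(self, rng):
        conf = np.repeat([0.0, 1.0], 10)
        col = np.tile([-1.0, 1.0], 10)  # orthogonal to the confound
        Z, _ = residualize_and_standardize(col[:, None], conf)
        direct = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(Z[:, 0], direct)

    def test_column_linear_in_confound_rejected(self):
        conf = np.arange(6.0)
        M = (2 * conf + 1)[:, None]
        with pytest.raises(ValueError, match="zero-variance"):
            residualize_and_standardize(M, conf)

    def test_rank_deficient_confounds_rejected(self, rng):
        conf = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(ValueError, match="rank deficient"):
            residualize_and_standardize(rng.normal(size=(8, 2)), conf)

    def test_stored_params_reapplied_without_refitting(self, rng):
        M = rng.normal(size=(30, 3))
        conf = rng.normal(size=30)
        _, params = residualize_and_standardize(M, conf)
        M2 = rng.normal(size=(10, 3))
        Z2, _ = residualize_and_standardize(M2, rng.normal(size=10), params)
        assert Z2.shape == (10, 3)  # applied, not refit: no unit-SD guarantee
        assert not np.allclose(Z2.std(axis=0, ddof=1), 1.0)


class TestPlscFit:
    def test_single_pair_sv_is_absolute_correlation(self, rng):
        x = rng.normal(size=200)
        y = -0.6 * x + rng.normal(size=200) * 0.5
        X, _ = residualize_and_standardize(x[:, None])
        Y, _ = residualize_and_standardize(y[:, None])
        r = np.corrcoef(x, y)[0, 1]
        fit = plsc_fit(X, Y)
        assert fit.singular_values[0] == pytest.approx(abs(r), abs=1e-10)
        assert abs(fit.x_weights[0, 0]) == 1.0

    def test_block_structure_svs_equal_block_correlations(self, rng):
        # two uncorrelated X columns, each driving one Y column
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        X, _ = residualize_and_standardize(np.column_stack([a, b]))
        Y, _ = residualize_and_standardize(
            np.column_stack(
                [a + rng.normal(size=n), b + 2 * rng.normal(size=n)]
            )
        )
        fit = plsc_fit(X, Y)
        R = cross_block_matrix(X, Y)
        assert np.sum(fit.singular_values**2) == pytest.approx(
            np.sum(R**2), abs=1e-9
        )

    def test_identical_blocks_perfect_association(self, rng):
        raw = rng.normal(size=(50, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q / q.std(axis=0, ddof=1)  # exactly orthogonal z-scored columns
        fit = plsc_fit(X, X)
        assert np.allclose(fit.singular_values, 1.0, atol=1e-9)
        assert np.allclose(np.abs(fit.x_scores), np.abs(fit.y_scores), atol=1e-8)

    def test_svd_identity_and_orthogonality(self, rng):
        X = rng.normal(size=(60, 7))
        Y = rng.normal(size=(60, 4))
        X, _ = residualize_and_standardize(X)
        Y, _ = residualize_and_standardize(Y)
        fit = plsc_fit(X, Y)
        R = cross_block_matrix(X, Y)
        assert np.sum(fit.singular_values**2) == pytest.approx(
            np.sum(R**2), abs=1e-9
        )
        assert np.allclose(
            fit.y_weights.T @ fit.y_weights, np.eye(4), atol=1e-10
        )
        # cross-side score orthogonality across dimensions
        cross = fit.x_scores.T @ fit.y_scores
        off = cross - np.diag(np.diag(cross))
        assert np.abs(off).max() < 1e-8

    def test_covariance_explained_sums_to_one(self, rng):
        X, _ = residualize_and_standardize(rng.normal(size=(40, 5)))
        Y, _ = residualize_and_standardize(rng.normal(size=(40, 3)))
        fit = plsc_fit(X, Y)
        assert fit.covariance_explained.sum() == pytest.approx(1.0)

    def test_planted_direction_recovered(self):
        data = simulate_linked_matrices(500, p=12, q=6, effect=1.0, seed=11)
        X, _ = residualize_lenient(data.X, None)
        Y, _ = residualize_lenient(data.Y, None)
        fit = plsc_fit(X, Y)
        assert abs(fit.x_weights[:, 0] @ data.x_direction) > 0.9
        assert abs(fit.y_weights[:, 0] @ data.y_direction) > 0.9


class TestPermutation:
    def test_minimum_attainable_pvalue(self):
        data = simulate_linked_matrices(300, effect=1.0, seed=5)
        X, _ = residualize_lenient(data.X, None)
        Y, _ = residualize_lenient(data.Y, None)
        res = permutation_test(X, Y, data.family_ids, n_perm=200, seed=0)
        assert res.pvalues[0] == pytest.approx(1 / 201)
        assert res.pvalues.min() >= 1 / 201

    def test_invariant_to_family_relabeling(self):
        data = simulate_linked_matrices(80, effect=0.3, seed=6)
        X, _ = residualize_lenient(data.X, None)
        Y, _ = residualize_lenient(data.Y, None)
        renamed = np.array([f"fam{f + 100}" for f in data.family_ids])
        p1 = permutation_test(X, Y, data.family_ids, n_perm=200, seed=3).pvalues
        p2 = permutation_test(X, Y, renamed, n_perm=200, seed=3).pvalues
        assert np.array_equal(p1, p2)

    def test_relatives_never_exchanged(self):
        from dfcstates.plsc import _block_permutation, exchangeability_blocks

        rng = np.random.default_rng(0)
        family_ids = np.repeat(np.arange(10), 3)
        blocks = exchangeability_blocks(family_ids, rng)
        for _ in range(20):
            perm = _block_permutation(30, blocks, rng)
            # a permuted row always replaces a member of a different family
            # or itself, never creates a within-family swap into one block
            for b in blocks:
                fams = family_ids[b]
                assert len(set(fams)) == len(fams)
                assert set(perm[b]) == set(b)


class TestBootstrap:
    def test_singleton_families_subject_bootstrap(self):
        data = simulate_linked_matrices(
            150, effect=1.0, family_size=1, seed=8
        )
        res = bootstrap_ratios(data.X, data.Y, data.family_ids, n_boot=100, seed=1)
        assert np.all(np.abs(res.x_ratios[data.planted_x, 0]) > 2.5)
        assert res.bootstrap_ratios.shape == (15, 5)

    def test_confound_refit_changes_ratios(self):
        data = simulate_linked_matrices(
            150, effect=1.0, confound_effect=1.5, seed=9
        )
        with_conf = bootstrap_ratios(
            data.X, data.Y, data.family_ids, n_boot=100, seed=2,
            confounds=data.confounds,
        )
        without = bootstrap_ratios(
            data.X, data.Y, data.family_ids, n_boot=100, seed=2
        )
        assert not np.allclose(
            with_conf.bootstrap_ratios, without.bootstrap_ratios
        )


class TestSplitHalf:
    def test_identical_test_half_reproduces_train_sv(self, rng):
        X, _ = residualize_lenient(rng.normal(size=(60, 6)), None)
        Y, _ = residualize_lenient(rng.normal(size=(60, 4)), None)
        fit = plsc_fit(X, Y)
        R = cross_block_matrix(X, Y)
        sv = projected_singular_values(fit.x_weights, fit.y_weights, R)
        assert np.allclose(sv, fit.singular_values, atol=1e-10)

    def test_oversized_family_rejected(self, rng):
        family_ids = np.array([0] * 70 + list(range(1, 31)))
        with pytest.raises(ValueError, match="half the cohort"):
            splithalf_reproducibility(
                rng.normal(size=(100, 4)),
                rng.normal(size=(100, 3)),
                family_ids,
                n_split=100,
            )


class TestCrossValidation:
    def test_leave_one_out_boundary(self):
        data = simulate_linked_matrices(
            30, p=4, q=3, effect=1.0, family_size=1, seed=12
        )
        res = cross_validate(
            data.X, data.Y, None, data.family_ids, n_folds=30, seed=0
        )
        assert res.oos_x_scores.shape == (30, 3)
        assert res.oos_correlation[0] > 0

    def test_shrinkage_direction_on_planted_association(self):
        data = simulate_linked_matrices(300, effect=1.0, seed=13)
        res = cross_validate(
            data.X, data.Y, None, data.family_ids, n_folds=10, seed=1
        )
        assert 0 < res.oos_correlation[0] < res.insample_correlation[0]

    def test_too_few_families_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer families"):
            cross_validate(
                rng.normal(size=(8, 3)),
                rng.normal(size=(8, 2)),
                None,
                np.zeros(8),
                n_folds=4,
            )


class TestVarianceExplained:
    def test_spanning_scores_explain_everything(self, rng):
        M = rng.normal(size=(20, 3))
        assert variance_explained(M, M.copy()) == pytest.approx(1.0)

    def test_orthogonal_scores_explain_nothing(self):
        M = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        scores = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        assert variance_explained(M, scores) == pytest.approx(0.0, abs=1e-12)

    def test_pc1_score_matches_eigen_ratio(self, rng):
        M = rng.normal(size=(100, 5)) @ np.diag([3, 1.5, 1, 0.5, 0.2])
        M = M - M.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(M.T @ M)
        pc1 = M @ eigvecs[:, -1]
        expected = eigvals[-1] / eigvals.sum()
        assert variance_explained(M, pc1[:, None]) == pytest.approx(expected)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            variance_explained(np.zeros((4, 2)), np.ones((4, 1)))
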