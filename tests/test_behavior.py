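"""Partial correlation, Rank-INT and PLSC: oracles, recovery, calibration."""

import numpy as np
import pytest
from scipy.special import ndtri

from dualpath.behavior import (behavior_matrix, partial_pearson, plsc,
                               rank_int, residualize)
from dualpath.synth import SyntheticSpec, generate_cohort


class TestResidualize:
    def test_covariate_column_gives_zero_residual(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=40)
        res = residualize(3 * z + 1, z)
        assert np.abs(res).max() < 1e-10

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(30, 4))
        cov = rng.normal(size=(30, 2))
        X = np.column_stack([np.ones(30), cov])
        P = np.eye(30) - X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(residualize(data, cov), P @ data, atol=1e-10)

    def test_no_covariates_is_demeaning(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=25)
        np.testing.assert_allclose(residualize(d, None), d - d.mean(), atol=1e-12)


class TestPartialPearson:
    def test_identical_series_r_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        r, p = partial_pearson(x, x.copy(), z)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_equals_residual_correlation_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 60))
        cov = rng.normal(size=(60, 2))
        r, _ = partial_pearson(x, y, cov)
        rx, ry = residualize(x, cov), residualize(y, cov)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_null_calibration_conditional_independence(self):
        # x and y both driven by z only: partial r should be near zero
        rng = np.random.default_rng(5)
        n, hits = 400, 0
        n_seeds = 200
        for _ in range(n_seeds):
            z = rng.normal(size=n)
            x = z + rng.normal(size=n)
            y = z + rng.normal(size=n)
            r, _ = partial_pearson(x, y, z)
            hits += abs(r) < 2 / np.sqrt(n)
        assert hits / n_seeds > 0.9

    def test_listwise_deletion_of_missing(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6, 7, 8])
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, np.nan])
        r, _ = partial_pearson(x, y, None)
        assert r == pytest.approx(1.0)


class TestRankInt:
    def test_blom_formula_oracle_n3(self):
        out = rank_int(np.array([5.0, 1.0, 9.0]))
        expected = ndtri((np.array([2, 1, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_middle_value_zero_and_symmetric_sum(self):
        rng = np.random.default_rng(6)
        v = rng.permutation(np.linspace(3, 90, 11))
        out = rank_int(v)
        assert out[np.argsort(v)[5]] == pytest.approx(0.0, abs=1e-12)
        assert out.sum() == pytest.approx(0.0, abs=1e-9)

    def test_monotone_for_tie_free_input(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=30)
        out = rank_int(v)
        assert (np.diff(out[np.argsort(v)]) > 0).all()

    def test_all_identical_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            out = rank_int(np.full(5, 2.0))
        np.testing.assert_array_equal(out, 0.0)


class TestPlsc:
    def _rank1_blocks(self, n=200, E=3, P=3, noise=0.5, seed=0):
        rng = np.random.default_rng(seed)
        w = np.array([1.0, 0.4, 0.8])
        w /= np.linalg.norm(w)
        X = rng.normal(size=(n, E))
        latent = X @ w
        u = np.array([0.9, 0.7, 0.5])
        Y = latent[:, None] * u[None, :] + noise * latent.std() * rng.normal(size=(n, P))
        return X, Y, w

    def test_recovers_planted_loading_direction(self):
        X, Y, w = self._rank1_blocks()
        res = plsc(X, Y, n_perm=200, n_boot=200, seed=1, apply_rank_int=False)
        cos = abs(res.brain_weights[:, 0] @ w)
        assert cos >= 0.9
        assert res.perm_p[0] < 0.01

    def test_weight_orthonormality_and_sign_convention(self):
        X, Y, _ = self._rank1_blocks(seed=2)
        res = plsc(X, Y, n_perm=0, n_boot=0, seed=0)
        np.testing.assert_allclose(res.brain_weights.T @ res.brain_weights,
                                   np.eye(3), atol=1e-8)
        np.testing.assert_allclose(res.behavior_weights.T @ res.behavior_weights,
                                   np.eye(3), atol=1e-8)
        for l in range(3):
            col = res.brain_weights[:, l]
            assert col[np.flatnonzero(np.abs(col) > 1e-12)[0]] > 0

    def test_univariate_case_reduces_to_partial_correlation(self):
        rng = np.random.default_rng(8)
        n = 80
        cov = rng.normal(size=(n, 2))
        x = rng.normal(size=n) + cov[:, 0]
        y = 0.6 * x + rng.normal(size=n)
        res = plsc(x, y, covariates=cov, n_perm=0, n_boot=0, seed=0,
                   apply_rank_int=False)
        r, _ = partial_pearson(x, y, cov)
        assert abs(res.lv_correlations[0]) == pytest.approx(abs(r), abs=1e-10)
        # with standardized blocks the singular value is |corr| of residuals
        assert res.singular_values[0] == pytest.approx(abs(r), abs=1e-10)

    def test_permutation_null_calibration(self):
        # independent blocks: LV1 permutation p should be uniform enough that
        # the 0.05-level rejection rate lands in 0.05 +/- 0.02 over 200 runs
        rng = np.random.default_rng(9)
        rejections = 0
        n_runs = 200
        for i in range(n_runs):
            X = rng.normal(size=(60, 3))
            Y = rng.normal(size=(60, 3))
            res = plsc(X, Y, n_perm=500, n_boot=0, seed=i, apply_rank_int=False)
            rejections += res.perm_p[0] < 0.05
        assert abs(rejections / n_runs - 0.05) <= 0.02

    def test_bsr_flags_planted_component_on_clean_data(self):
        X, Y, _ = self._rank1_blocks(noise=0.05, seed=3)
        res = plsc(X, Y, n_perm=0, n_boot=500, seed=4, apply_rank_int=False)
        assert res.significant_brain()[np.abs(res.brain_weights[:, 0]) > 0.3, 0].all()

    def test_permutation_p_invariant_to_joint_row_permutation(self):
        X, Y, _ = self._rank1_blocks(n=60, seed=5)
        res1 = plsc(X, Y, n_perm=300, n_boot=0, seed=11, apply_rank_int=False)
        perm = np.random.default_rng(12).permutation(60)
        res2 = plsc(X[perm], Y[perm], n_perm=300, n_boot=0, seed=11,
                    apply_rank_int=False)
        np.testing.assert_allclose(res1.perm_p, res2.perm_p, atol=0.03)
        np.testing.assert_allclose(res1.singular_values, res2.singular_values,
                                   atol=1e-10)

    def test_constant_behavior_column_dropped(self):
        X, Y, _ = self._rank1_blocks(n=50, seed=6)
        Y[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = plsc(X, Y, n_perm=0, n_boot=0, seed=0, apply_rank_int=False)
        assert res.behavior_weights.shape[0] == 2


def _tiny_spec(n=5, seed=0):
    from dualpath.synth import EventSpec
    return SyntheticSpec(n_per_group=n, n_regions=8, n_timepoints=40, seed=seed,
                         trait_rois=(0, 1), events=(EventSpec(10, 20, (3, 4)),
                                                    EventSpec(25, 35, (5, 6))))


class TestBehaviorMatrix:
    def test_default_columns_and_missing_mask(self):
        cohort, _ = generate_cohort(_tiny_spec())
        M, mask = behavior_matrix(cohort)
        assert M.shape == (10, 3)
        assert mask.all()
        # knock one score out
        cohort.records[3].behavior["SRS_total"] = float("nan")
        M, mask = behavior_matrix(cohort)
        assert mask.sum() == 9 and not mask[3]

    def test_column_order_follows_request(self):
        cohort, _ = generate_cohort(_tiny_spec(n=3))
        M1, _ = behavior_matrix(cohort, ["CBCL_total", "SRS_total"])
        M2, _ = behavior_matrix(cohort, ["SRS_total", "CBCL_total"])
        np.testing.assert_allclose(M1[:, 0], M2[:, 1])

    def test_fully_missing_score_errors(self):
        cohort, _ = generate_cohort(_tiny_spec(n=3))
        with pytest.raises(ValueError, match="missing"):
            behavior_matrix(cohort, ["nonexistent_scale"])
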