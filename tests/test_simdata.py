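"""Synthetic covariate/outcome generator: structure, calibration, splits."""
import numpy as np
import pytest
from scipy import stats

from censelect import (
    CovariateDesign,
    TruthSpec,
    build_covariance,
    calibrate_effect_size,
    choose_true_variables,
    impute_and_standardize,
    sample_covariates,
    simulate_outcome,
    split_discovery_validation,
)
from censelect.simdata import CovariateMatrix


class TestBuildCovariance:
    def test_single_block_construction(self):
        d = CovariateDesign(p=10, n=100, blocks=((5, 0.97),))
        C = build_covariance(d)
        block = C[:5, :5]
        assert np.allclose(block[~np.eye(5, dtype=bool)], 0.97)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C[5:, :5], 0.0)

    def test_no_blocks_identity(self):
        C = build_covariance(CovariateDesign(p=7, n=50))
        assert np.allclose(C, np.eye(7))

    def test_extreme_block_stays_psd(self):
        d = CovariateDesign(p=60, n=100, blocks=((50, 0.999),), background=0.3)
        C = build_covariance(d)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestSampleCovariates:
    def test_block_spearman_near_target(self, block_X):
        rho = stats.spearmanr(block_X.values[:, :5]).statistic
        off = np.abs(rho[np.triu_indices(5, 1)])
        assert off.min() > 0.92 and off.max() <= 1.0

    def test_standardized_columns(self, block_X):
        V = block_X.values
        assert np.abs(V.mean(axis=0)).max() < 1e-8
        assert np.abs(V.std(axis=0, ddof=1) - 1).max() < 1e-8
        assert not np.isnan(V).any()

    def test_zero_inflation_fraction(self):
        d = CovariateDesign(p=4, n=2000, marginal_spec={0: ("zero_inflated", 0.5)},
                            seed=3)
        X = sample_covariates(d)
        col = X.values[:, 0]
        # zeros map to the column minimum after standardization
        frac = np.mean(col == col.min())
        assert abs(frac - 0.5) < 0.03

    def test_no_missing_means_pure_transform(self):
        d = CovariateDesign(p=5, n=200, missing_rate=0.0, seed=7)
        X = sample_covariates(d)
        # re-standardizing is a no-op: imputation changed nothing
        again = impute_and_standardize(X.values, names=X.names)
        assert np.allclose(again.values, X.values, atol=1e-12)


class TestImputeStandardize:
    def test_median_imputation(self):
        out = impute_and_standardize(np.array([[1.0], [np.nan], [3.0]]))
        # median 2 imputed -> column (1,2,3) standardized
        expect = (np.array([1.0, 2.0, 3.0]) - 2.0) / 1.0
        assert np.allclose(out.values[:, 0], expect)

    def test_idempotent(self, rng):
        raw = rng.standard_normal((50, 3))
        once = impute_and_standardize(raw)
        twice = impute_and_standardize(once.values)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_spike_column_hand_arithmetic(self):
        out = impute_and_standardize(np.array([[0.0], [0.0], [0.0], [0.0], [10.0]]))
        # mean 2, sd sqrt(20) with ddof=1
        assert np.allclose(out.values[:, 0],
                           np.array([-2, -2, -2, -2, 8]) / np.sqrt(20))

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="V0002"):
            impute_and_standardize(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_commutes_with_permutation(self, rng):
        raw = rng.standard_normal((40, 5))
        perm = rng.permutation(5)
        a = impute_and_standardize(raw).values[:, perm]
        b = impute_and_standardize(raw[:, perm]).values
        assert np.allclose(a, b)


class TestChooseTrueVariables:
    def test_identity_correlation_errors(self, indep_X):
        with pytest.raises(ValueError, match="pool"):
            choose_true_variables(indep_X, seed=0)

    def test_forced_block_pick(self, block_X):
        truth = choose_true_variables(block_X, seed=0, family="continuous")
        assert sorted(truth.true_indices[:5]) == [0, 1, 2, 3, 4]

    def test_pools_match_bruteforce_scan(self, block_X):
        V = block_X.values
        p = V.shape[1]
        C = np.corrcoef(V, rowvar=False)
        high, low = [], []
        for j in range(p):  # O(p^2) oracle scan
            m = max(abs(C[j, k]) for k in range(p) if k != j)
            if m > 0.95:
                high.append(j)
            if m < 0.6:
                low.append(j)
        truth = choose_true_variables(block_X, seed=4, family="continuous")
        assert set(truth.true_indices[:5]) <= set(high)
        assert set(truth.true_indices[5:]) <= set(low)


class TestCalibrateEffectSize:
    def test_closed_form_alpha005(self):
        # independent closed form: (z_{.025} + z_{.8}) / sqrt(n), rounded up
        expect = np.ceil((stats.norm.isf(0.025) + stats.norm.ppf(0.8))
                         / np.sqrt(2000) * 100) / 100
        assert calibrate_effect_size("continuous", 2000, 0.80, 0.05) == expect

    def test_monotone_in_n_and_alpha(self):
        b1 = calibrate_effect_size("binary", 1000, 0.8, 5e-5)
        b2 = calibrate_effect_size("binary", 4000, 0.8, 5e-5)
        b3 = calibrate_effect_size("binary", 1000, 0.8, 0.05)
        assert b2 < b1 and b3 < b1

    def test_infeasible_raises(self):
        with pytest.raises(ValueError):
            calibrate_effect_size("binary", 2, 0.999999, 1e-300)


class TestSimulateOutcome:
    def _truth(self, X, beta, family):
        return TruthSpec(tuple(range(10)), beta, family)

    def test_null_binary_prevalence(self, indep_X):
        X = CovariateMatrix(np.tile(indep_X.values, (1, 1)), indep_X.names)
        truth = TruthSpec(tuple(range(10)), 0.0, "binary")
        y = simulate_outcome(indep_X, truth, seed=1).y
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert abs(y.mean() - 0.5) < 3 * 0.5 / np.sqrt(len(y))

    def test_null_continuous_unit_variance(self, indep_X):
        truth = TruthSpec(tuple(range(10)), 0.0, "continuous")
        y = simulate_outcome(indep_X, truth, seed=2).y
        assert abs(y.var(ddof=1) - 1.0) < 0.2

    def test_ols_recovers_beta_monte_carlo(self):
        # a low-collinearity truth's univariable slope is unbiased for beta
        design = CovariateDesign(p=12, n=2000, seed=9)
        X = sample_covariates(design)
        truth = TruthSpec(tuple(range(10)), 0.11, "continuous")
        slopes = []
        for s in range(200):
            y = simulate_outcome(X, truth, seed=s).y
            x = X.values[:, 11]  # null variable check would be 0; use truth 9
            xt = X.values[:, 9]
            b = (xt - xt.mean()) @ (y - y.mean()) / ((xt - xt.mean()) @ (xt - xt.mean()))
            slopes.append(b)
        assert abs(np.mean(slopes) - 0.11) < 0.01

    def test_deterministic_given_seed(self, indep_X):
        truth = TruthSpec(tuple(range(10)), 0.5, "binary")
        y1 = simulate_outcome(indep_X, truth, seed=7).y
        y2 = simulate_outcome(indep_X, truth, seed=7).y
        assert np.array_equal(y1, y2)


class TestSplit:
    def test_reference_dimensions(self):
        s = split_discovery_validation(2000, seed=0)
        assert len(s.discovery_idx) == 1333 and len(s.validation_idx) == 667

    def test_tiny_n(self):
        s = split_discovery_validation(3, seed=1)
        assert {len(s.discovery_idx), len(s.validation_idx)} == {2, 1}

    def test_partition_and_determinism(self):
        a = split_discovery_validation(101, seed=3)
        b = split_discovery_validation(101, seed=3)
        assert np.array_equal(a.discovery_idx, b.discovery_idx)
        union = np.union1d(a.discovery_idx, a.validation_idx)
        assert np.array_equal(union, np.arange(101))
        assert len(np.intersect1d(a.discovery_idx, a.validation_idx)) == 0
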