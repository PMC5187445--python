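"""Lagged design, ridge estimation, jackknife CV and model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strfshift import strf as ST
from strfshift.synthetic import simulate_hfb

LAGS4 = np.arange(4) / 50.0


def _toy_fit(fold_r2):
    """STRFFit stub with only the scoring fields populated."""
    fold_r2 = np.asarray(fold_r2, dtype=float)
    return ST.STRFFit(
        gain=np.zeros((2, 2)),
        fold_gains=np.zeros((len(fold_r2), 2, 2)),
        tmap=np.zeros((2, 2)),
        ridge=1.0,
        fold_r2=fold_r2,
        ci_lower_r2=float(np.percentile(fold_r2, 0.5)),
    )


class TestLaggedDesign:
    def test_one_hot_gain_reproduces_shifted_band(self, rng):
        S = rng.random((60, 5))
        X = ST.build_lagged_design(S, LAGS4, 50.0)
        g = np.zeros((4, 5))
        g[2, 3] = 1.0
        out = X @ g.ravel()
        assert np.array_equal(out[2:], S[:-2, 3])
        assert np.all(out[:2] == 0.0)

    def test_default_shape(self, rng):
        S = rng.random((100, 32))
        X = ST.build_lagged_design(S)
        assert X.shape == (100, 21 * 32)

    def test_first_row_nonzero_only_at_lag_zero(self, rng):
        S = rng.random((30, 4)) + 0.5
        X = ST.build_lagged_design(S, LAGS4, 50.0)
        assert np.all(X[0, 4:] == 0.0)
        assert np.all(X[0, :4] == S[0])

    def test_off_grid_lag_raises(self):
        with pytest.raises(ValueError):
            ST.build_lagged_design(np.zeros((10, 2)), np.array([0.013]), 50.0)


class TestFitRidge:
    def test_zero_penalty_matches_ols(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        w0 = ST.fit_ridge(X, y, 0.0)
        w_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(w0, w_ols, atol=1e-8)

    def test_large_penalty_shrinks_to_zero(self, rng):
        X = rng.standard_normal((50, 5))
        y = rng.standard_normal(50)
        assert np.linalg.norm(ST.fit_ridge(X, y, 1e12)) < 1e-6

    def test_orthonormal_design_closed_form(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((60, 5)))
        y = rng.standard_normal(60)
        lam = 2.5
        w_ols = ST.fit_ridge(Q, y, 0.0)
        assert np.allclose(ST.fit_ridge(Q, y, lam), w_ols / (1 + lam), atol=1e-10)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        for lam in (0.1, 3.0, 100.0):
            direct = np.linalg.solve(X.T @ X + lam * np.eye(12), X.T @ y)
            assert np.allclose(ST.fit_ridge(X, y, lam), direct, atol=1e-8)

    def test_matches_sklearn(self, rng):
        from sklearn.linear_model import Ridge

        X = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        sk = Ridge(alpha=7.0, fit_intercept=False, solver="svd").fit(X, y)
        assert np.allclose(ST.fit_ridge(X, y, 7.0), sk.coef_, atol=1e-8)

    def test_negative_penalty_raises(self):
        with pytest.raises(ValueError):
            ST.fit_ridge(np.eye(3), np.ones(3), -1.0)


class TestJackknife:
    def _noiseless_trials(self, stims, g):
        return [
            (S, ST.build_lagged_design(S, LAGS4, 50.0) @ g.ravel()) for S in stims
        ]

    def test_noiseless_recovery(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        trials = self._noiseless_trials(random_auditory_stims, g)
        fit = ST.fit_strf_jackknife(trials, lags_s=LAGS4)
        g_std = ST.truth_on_standardized_scale(g, random_auditory_stims, LAGS4, 50.0)
        assert np.corrcoef(fit.gain.ravel(), g_std.ravel())[0, 1] >= 0.99
        assert np.corrcoef(fit.gain_raw.ravel(), g.ravel())[0, 1] >= 0.99

    def test_null_target_scores_nonpositive(self, random_auditory_stims, rng):
        trials = [(S, rng.standard_normal(S.shape[0])) for S in random_auditory_stims]
        fit = ST.fit_strf_jackknife(trials, lags_s=LAGS4)
        assert fit.fold_r2.mean() <= 0.0
        assert fit.ci_lower_r2 < 0.0

    def test_trial_order_invariance(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        trials = self._noiseless_trials(random_auditory_stims, g)
        f1 = ST.fit_strf_jackknife(trials, ridge=1.0, lags_s=LAGS4)
        f2 = ST.fit_strf_jackknife(trials[::-1], ridge=1.0, lags_s=LAGS4)
        assert np.allclose(f1.gain, f2.gain, atol=1e-10)

    def test_duplicating_trials_leaves_gain_unchanged(self, rng):
        # well-conditioned (white) stimuli so the noiseless solution is
        # unique and the estimator's symmetry is exact
        stims = [rng.random((120, 8)) for _ in range(5)]
        g = rng.standard_normal((4, 8))
        trials = self._noiseless_trials(stims, g)
        f1 = ST.fit_strf_jackknife(trials, ridge=1e-10, lags_s=LAGS4)
        f2 = ST.fit_strf_jackknife(trials + trials, ridge=1e-10, lags_s=LAGS4)
        # raw-scale coefficients are standardization-free, so the
        # noiseless identifiable solution is identical
        assert np.allclose(f1.gain_raw, f2.gain_raw, atol=1e-8)

    def test_too_few_trials_raises(self, random_auditory_stims):
        with pytest.raises(ValueError):
            ST.fit_strf_jackknife([(random_auditory_stims[0], np.zeros(120))])

    def test_heldout_r2_decreases_with_noise(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        means = []
        for snr in (np.inf, 8.0, 4.0, 2.0, 1.0):
            trials = [
                (S, simulate_hfb(g, S, snr, seed=i, rate=50.0))
                for i, S in enumerate(random_auditory_stims)
            ]
            fit = ST.fit_strf_jackknife(trials, lags_s=LAGS4)
            means.append(fit.fold_r2.mean())
        se = np.std(means) / 2  # loose one-simulation tolerance
        assert all(a >= b - max(se, 0.05) for a, b in zip(means, means[1:]))


class TestSelection:
    def test_global_ridge_mode(self):
        assert ST.select_global_ridge([1, 1, 10]) == 1
        assert ST.select_global_ridge([1, 10, 10, 1]) == 10  # tie -> larger
        assert ST.select_global_ridge([31.6]) == 31.6

    def test_strf_responsive(self):
        assert ST.select_strf_responsive(_toy_fit([0.3] * 8))
        assert not ST.select_strf_responsive(_toy_fit([-0.2, -0.1, 0.1, 0.2]))


class TestPredictAndScore:
    def test_zero_gain_zero_trace(self, rng):
        S = rng.random((50, 6))
        assert np.all(ST.predict_hfb(np.zeros((4, 6)), S, lags_s=LAGS4) == 0.0)

    def test_one_hot_gain_shifted_band(self, rng):
        S = rng.random((50, 6))
        g = np.zeros((4, 6))
        g[1, 2] = 1.0
        out = ST.predict_hfb(g, S, lags_s=LAGS4, standardize=False)
        assert np.array_equal(out[1:], S[:-1, 2])

    def test_training_prediction_noiseless(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        trials = [
            (S, ST.build_lagged_design(S, LAGS4, 50.0) @ g.ravel())
            for S in random_auditory_stims
        ]
        fit = ST.fit_strf_jackknife(trials, lags_s=LAGS4)
        S, r = trials[0]
        pred = ST.predict_hfb(fit, S, lags_s=LAGS4)
        rz = (r - r.mean()) / r.std()
        assert ST.score_r2(pred, rz) >= 0.99

    def test_score_r2_reference_points(self, rng):
        y = rng.standard_normal(100)
        assert ST.score_r2(y, y) == 1.0
        assert abs(ST.score_r2(np.full_like(y, y.mean()), y)) < 1e-12
        y0 = y - y.mean()
        assert np.isclose(ST.score_r2(-y0, y0), -3.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_score_r2_shift_invariance(self, seed):
        """R^2 is invariant to adding a common constant to both traces."""
        r = np.random.default_rng(seed)
        y = r.standard_normal(30)
        p = y + 0.1 * r.standard_normal(30)
        c = r.standard_normal()
        assert np.isclose(ST.score_r2(p, y), ST.score_r2(p + c, y + c), atol=1e-10)
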