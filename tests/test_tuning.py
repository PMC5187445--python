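"""MTF, output power, generalization and partial-correlation contrasts."""

import numpy as np
import pytest

from strfshift import strf as ST
from strfshift import tuning as TU

GEO_CENTERS = np.geomspace(200.0, 6400.0, 32)  # exactly logarithmic


def _log_gabor(n_lags=21, n_bands=32, f_tau=6.0, cycles_per_step=0.1, lag_step=0.02):
    """Separable Gabor on a uniform-log band grid with known carriers."""
    tau = np.arange(n_lags)[:, None] * lag_step
    band = np.arange(n_bands)[None, :]
    env = np.exp(
        -((tau - 0.2) ** 2) / (2 * 0.07**2) - ((band - 16) ** 2) / (2 * 6.0**2)
    )
    return env * np.cos(2 * np.pi * f_tau * tau) * np.cos(
        2 * np.pi * cycles_per_step * band
    )


class TestMTF:
    def test_delta_filter_flat_mtf(self):
        g = np.zeros((21, 32))
        g[5, 12] = 1.0
        mtf = TU.strf_mtf(g, band_centers=GEO_CENTERS, n_log_bands=32)
        assert np.allclose(mtf.amplitude, mtf.amplitude.flat[0], atol=1e-9)

    def test_gabor_peak_location(self):
        d_log = np.log10(GEO_CENTERS[1]) - np.log10(GEO_CENTERS[0])
        cycles_per_step = 0.1
        g = _log_gabor(f_tau=6.0, cycles_per_step=cycles_per_step)
        mtf = TU.strf_mtf(g, band_centers=GEO_CENTERS, n_log_bands=32)
        i, j = np.unravel_index(mtf.amplitude.argmax(), mtf.amplitude.shape)
        assert abs(abs(mtf.wt[i]) - 6.0) <= (mtf.wt[1] - mtf.wt[0])
        expected_wf = (cycles_per_step / d_log) / np.log(10.0)  # cycles/kHz at 1 kHz
        assert abs(mtf.wf[j] - expected_wf) <= (mtf.wf[1] - mtf.wf[0])

    def test_time_reversal_mirrors_temporal_axis(self, rng):
        g = rng.standard_normal((21, 32))
        m1 = TU.strf_mtf(g, band_centers=GEO_CENTERS, n_log_bands=32)
        m2 = TU.strf_mtf(g[::-1], band_centers=GEO_CENTERS, n_log_bands=32)
        # wt -> -wt; the roll accounts for the even-length fftshift grid
        mirrored = np.roll(m1.amplitude[::-1], 1, axis=0)
        assert np.allclose(m2.amplitude, mirrored, atol=1e-9)

    def test_condition_contrast_properties(self, rng):
        def fit_with(gain):
            return ST.STRFFit(
                gain=gain, fold_gains=gain[None], tmap=gain, ridge=1.0,
                fold_r2=np.zeros(2), ci_lower_r2=0.0,
            )

        gains = [rng.standard_normal((21, 32)) for _ in range(3)]
        fits = {
            "before": [fit_with(g) for g in gains],
            "after": [fit_with(g + 0.5) for g in gains],
        }
        same = {"before": fits["before"], "after": fits["before"]}
        res = TU.mtf_condition_contrast(same)
        assert np.allclose(res["maps"], 0.0)
        r1 = TU.mtf_condition_contrast(fits)
        r2 = TU.mtf_condition_contrast(fits, conditions=("before", "after"))
        assert np.allclose(r1["maps"], -r2["maps"], atol=1e-9)

    def test_filter_type_contrast_antisymmetric(self, rng):
        base = {"maps": rng.standard_normal((3, 16, 9)),
                "wt": np.arange(16), "wf": np.arange(9)}
        other = {"maps": rng.standard_normal((3, 16, 9)),
                 "wt": np.arange(16), "wf": np.arange(9)}
        d1 = TU.mtf_filter_type_contrast(base, other)
        d2 = TU.mtf_filter_type_contrast(other, base)
        assert np.allclose(d1["maps"], -d2["maps"], atol=1e-12)
        same = TU.mtf_filter_type_contrast(base, base)
        assert np.allclose(same["maps"], 0.0)


class TestOutputPower:
    def test_zero_strf_raises(self, random_auditory_stims):
        with pytest.raises(ValueError):
            TU.speech_output_power(np.zeros((4, 8)), random_auditory_stims)

    def test_matched_filter_beats_random(self, random_auditory_stims, rng):
        # the output-power maximizer over zero-mean unit filters is the
        # top eigendirection of the standardized-feature covariance,
        # restricted to the demeaned subspace (the measure z-scores the
        # filter first)
        lags = np.arange(4) / 50.0
        X = np.vstack(
            [ST.build_lagged_design(S, lags, 50.0) for S in random_auditory_stims]
        )
        Xz = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        D = Xz.shape[1]
        J = np.eye(D) - np.ones((D, D)) / D
        evals, evecs = np.linalg.eigh(J @ (Xz.T @ Xz) @ J)
        matched = evecs[:, -1].reshape(4, 8)
        rms_m = TU.speech_output_power(matched, random_auditory_stims, rate=50.0)
        wins = 0
        for _ in range(100):
            g = rng.standard_normal((4, 8))
            wins += rms_m > TU.speech_output_power(g, random_auditory_stims, rate=50.0)
        assert wins == 100

    def test_linearity_in_stimulus_amplitude(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        r1 = TU.speech_output_power(
            g, random_auditory_stims, rate=50.0, standardize=False
        )
        r2 = TU.speech_output_power(
            g, [2 * S for S in random_auditory_stims], rate=50.0, standardize=False
        )
        assert np.isclose(r2, 2 * r1)

    def test_concatenate_vs_average_switch(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        a = TU.speech_output_power(g, random_auditory_stims, rate=50.0, concatenate=False)
        b = TU.speech_output_power(g, random_auditory_stims, rate=50.0, concatenate=True)
        assert np.isfinite(a) and np.isfinite(b)


class TestGeneralization:
    def test_observed_equals_predicted_gives_one(self, random_auditory_stims, rng):
        g = rng.standard_normal((4, 8))
        fit = g  # bare gain tensor path
        preds = [
            ST.predict_hfb(g, S, rate=50.0, lags_s=np.arange(4) / 50.0)
            for S in random_auditory_stims
        ]
        r2 = TU.generalization_score(fit, random_auditory_stims, preds, rate=50.0)
        assert np.isclose(r2, 1.0, atol=1e-10)


class TestPartialCorrelation:
    def test_closed_form_oracle(self, rng):
        # exact sample correlation structure via an orthonormal basis
        r_ab, r_ac, r_bc = 0.6, 0.5, 0.5
        R = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1]])
        L = np.linalg.cholesky(R)
        Q, _ = np.linalg.qr(rng.standard_normal((60, 3)))
        Q = Q - Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)  # orthonormal and mean-free
        a, b, c = (Q @ L.T).T
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert abs(TU.partial_correlation(a, b, c) - expected) < 1e-10

    def test_identical_inputs_orthogonal_condition(self, rng):
        a = rng.standard_normal(50)
        c = rng.standard_normal(50)
        c = c - c @ a / (a @ a) * a  # orthogonalize
        assert TU.partial_correlation(a, a, c) > 0.999

    def test_input_equal_to_conditioned_gives_zero(self, rng):
        c = rng.standard_normal(50)
        b = rng.standard_normal(50)
        assert TU.partial_correlation(c, b, c) == 0.0

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            TU.partial_correlation(np.ones(10), np.arange(10), np.arange(10))


class TestTuningShiftContrast:
    def _fits(self, rng, shift=0.0):
        def fit_with(tmap):
            return ST.STRFFit(
                gain=tmap, fold_gains=tmap[None], tmap=tmap, ridge=1.0,
                fold_r2=np.zeros(2), ci_lower_r2=0.0,
            )

        out = {"before": [], "middle": [], "after": []}
        for _ in range(4):
            b = rng.standard_normal((21, 32))
            m = rng.standard_normal((21, 32))
            a = (1 - shift) * b + shift * m + 0.1 * rng.standard_normal((21, 32))
            out["before"].append(fit_with(b))
            out["middle"].append(fit_with(m))
            out["after"].append(fit_with(a))
        return out

    def test_condition_swap_negates(self, rng):
        fits = self._fits(rng, shift=0.7)
        d1 = TU.tuning_shift_contrast(fits)
        swapped = dict(fits, before=fits["after"], after=fits["before"])
        d2 = TU.tuning_shift_contrast(swapped)
        assert np.allclose(d1, -d2, atol=1e-12)

    def test_shift_toward_middle_gives_positive_delta(self, rng):
        d = TU.tuning_shift_contrast(self._fits(rng, shift=0.8))
        assert np.all(d > 0)

    def test_feature_order_invariance(self, rng):
        fits = self._fits(rng, shift=0.5)
        d1 = TU.tuning_shift_contrast(fits)
        perm = rng.permutation(21 * 32)

        def permute(fit):
            t = fit.tmap.ravel()[perm].reshape(21, 32)
            return ST.STRFFit(
                gain=t, fold_gains=t[None], tmap=t, ridge=1.0,
                fold_r2=np.zeros(2), ci_lower_r2=0.0,
            )

        fits_p = {c: [permute(f) for f in fs] for c, fs in fits.items()}
        assert np.allclose(TU.tuning_shift_contrast(fits_p), d1, atol=1e-10)
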