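"""Quantifying eSTRF tuning shifts between conditions.

Four complementary measures ask whether the receptive field estimated
after experience with clean speech (AFTER) has moved toward the
clean-speech receptive field (MIDDLE), relative to the naive estimate
(BEFORE):

* the modulation transfer function (MTF) of each eSTRF, comparable to
  the stimulus modulation power spectrum;
* the RMS output power of each filtered-speech eSTRF driven by
  unfiltered-speech spectrograms (a matched-filter overlap measure);
* the generalization R^2 of MIDDLE-condition coefficients predicting
  the filtered-condition responses;
* the partial correlation between condition eSTRFs, conditioning on the
  third condition, whose difference

      delta_rho = rho(AFTER, MIDDLE | BEFORE) - rho(BEFORE, MIDDLE | AFTER)

  is the headline tuning-shift statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from strfshift.auditory import default_band_centers
from strfshift.strf import STRFFit, predict_hfb, score_r2

__all__ = [
    "MTF",
    "strf_mtf",
    "mtf_condition_contrast",
    "mtf_filter_type_contrast",
    "speech_output_power",
    "generalization_score",
    "partial_correlation",
    "tuning_shift_contrast",
]

#: conversion from cycles/decade (log10-frequency) to the cycles/kHz
#: scale of the stimulus MPS, linearized at the 1 kHz reference
_CYC_PER_DECADE_TO_CYC_PER_KHZ = 1.0 / np.log(10.0)


@dataclass
class MTF:
    """Modulation transfer function of a spectrotemporal filter.

    ``amplitude`` is temporal modulation (signed, Hz) x spectral
    modulation (>= 0).  The spectral axis is in cycles/kHz linearized at
    1 kHz after resampling the band axis onto a uniform log-frequency
    grid, which makes it comparable to the stimulus MPS.
    """

    amplitude: np.ndarray
    wt: np.ndarray
    wf: np.ndarray


def strf_mtf(
    gain: np.ndarray,
    lag_step_s: float = 0.02,
    band_centers: np.ndarray | None = None,
    n_log_bands: int = 64,
    pad_factor: int = 4,
) -> MTF:
    """MTF: amplitude of the 2D Fourier transform of a STRF.

    The band axis is first interpolated onto a uniform log-frequency
    grid (ERB spacing is close to, but not exactly, logarithmic); both
    axes are zero-padded by ``pad_factor`` for a smooth spectrum.
    """
    g = np.asarray(gain, dtype=float)
    n_lags, n_bands = g.shape
    if band_centers is None:
        band_centers = default_band_centers(n_bands)
    logf = np.log10(np.asarray(band_centers, dtype=float))
    grid = np.linspace(logf[0], logf[-1], n_log_bands)
    g_log = np.empty((n_lags, n_log_bands))
    for i in range(n_lags):
        g_log[i] = np.interp(grid, logf, g[i])

    nt = pad_factor * n_lags
    nf = pad_factor * n_log_bands
    F = np.fft.fft2(g_log, s=(nt, nf))
    n_keep = nf // 2 + 1
    amp = np.abs(np.fft.fftshift(F, axes=0)[:, :n_keep])
    wt = np.fft.fftshift(np.fft.fftfreq(nt, d=lag_step_s))
    d_log = grid[1] - grid[0]
    wf = np.fft.rfftfreq(nf, d=d_log) * _CYC_PER_DECADE_TO_CYC_PER_KHZ
    return MTF(amplitude=amp, wt=wt, wf=wf)


def mtf_condition_contrast(
    fits_by_condition: dict[str, list[STRFFit]],
    conditions: tuple[str, str] = ("after", "before"),
    **mtf_kwargs,
) -> dict:
    """Per-electrode MTF difference maps, z-scored within electrode.

    Returns maps for ``conditions[0] - conditions[1]`` (AFTER - BEFORE
    by default); group-level inference on the maps is delegated to the
    stats module.
    """
    a_fits = fits_by_condition[conditions[0]]
    b_fits = fits_by_condition[conditions[1]]
    maps = []
    axes = None
    for fa, fb in zip(a_fits, b_fits):
        ma = strf_mtf(fa.gain, **mtf_kwargs)
        mb = strf_mtf(fb.gain, **mtf_kwargs)
        d = ma.amplitude - mb.amplitude
        s = d.std()
        maps.append((d - d.mean()) / s if s > 0 else np.zeros_like(d))
        axes = (ma.wt, ma.wf)
    return {"maps": np.array(maps), "wt": axes[0], "wf": axes[1]}


def mtf_filter_type_contrast(maps_temporal: dict, maps_spectral: dict) -> dict:
    """Per-electrode MTF difference between filter-type experiments
    (temporal-filtered minus spectral-filtered), z-scored within
    electrode.

    Both inputs are outputs of :func:`mtf_condition_contrast` computed
    on experiments that used the respective stimulus filter; electrodes
    must correspond one-to-one.
    """
    a = np.asarray(maps_temporal["maps"], dtype=float)
    b = np.asarray(maps_spectral["maps"], dtype=float)
    if a.shape != b.shape:
        raise ValueError("filter-type map stacks must have matching shapes")
    d = a - b
    out = np.empty_like(d)
    for i, m in enumerate(d):
        s = m.std()
        out[i] = (m - m.mean()) / s if s > 0 else 0.0
    return {"maps": out, "wt": maps_temporal["wt"], "wf": maps_temporal["wf"]}


def speech_output_power(
    gain: np.ndarray | STRFFit,
    spectrograms: list[np.ndarray],
    rate: float = 50.0,
    concatenate: bool = True,
    standardize: bool = True,
) -> float:
    """RMS of the eSTRF's predicted response to unfiltered speech.

    The gain tensor is z-scored first (so only the shape of the filter
    matters, not its overall magnitude), each spectrogram is
    standardized as in fitting, and the RMS is taken over the
    concatenated predicted traces (or averaged per sentence with
    ``concatenate=False``).
    """
    g = gain.gain if isinstance(gain, STRFFit) else np.asarray(gain, dtype=float)
    s = g.std()
    if s == 0:
        raise ValueError("cannot z-score a constant (zero-variance) STRF")
    gz = (g - g.mean()) / s
    outs = [predict_hfb(gz, S, rate=rate, standardize=standardize) for S in spectrograms]
    if concatenate:
        return float(np.sqrt(np.mean(np.concatenate(outs) ** 2)))
    return float(np.mean([np.sqrt(np.mean(o**2)) for o in outs]))


def generalization_score(
    fit_middle: STRFFit | np.ndarray,
    stimuli: list[np.ndarray],
    responses: list[np.ndarray],
    rate: float = 50.0,
) -> float:
    """How well MIDDLE-condition coefficients predict filtered-condition
    HFB.

    Predicted and observed traces are both z-scored per trial (the model
    works on the standardized scale throughout) and a single R^2 is
    computed over the concatenation.
    """

    def _z(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    preds, obs = [], []
    for S, r in zip(stimuli, responses):
        preds.append(_z(predict_hfb(fit_middle, S, rate=rate, standardize=True)))
        obs.append(_z(r))
    return score_r2(np.concatenate(preds), np.concatenate(obs))


def partial_correlation(
    a: np.ndarray,
    b: np.ndarray,
    conditioned: np.ndarray,
) -> float:
    """Correlation of a and b after regressing out the conditioned
    variable (least squares with intercept) from both.

    Degenerate (zero-variance) inputs raise ``ValueError``.  If an input
    is perfectly collinear with the conditioned variable its residual
    vanishes and no linear relation remains, so the partial correlation
    is reported as 0.
    """
    av = np.asarray(a, dtype=float).ravel()
    bv = np.asarray(b, dtype=float).ravel()
    cv = np.asarray(conditioned, dtype=float).ravel()
    if not (av.size == bv.size == cv.size):
        raise ValueError("a, b and conditioned must have equal lengths")
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("zero-variance input: partial correlation undefined")
    C = np.column_stack([np.ones(cv.size), cv])
    coef_a, *_ = np.linalg.lstsq(C, av, rcond=None)
    coef_b, *_ = np.linalg.lstsq(C, bv, rcond=None)
    ra = av - C @ coef_a
    rb = bv - C @ coef_b
    tol_a = 1e-12 * av.std()
    tol_b = 1e-12 * bv.std()
    if ra.std() <= tol_a or rb.std() <= tol_b:
        return 0.0
    return float(np.corrcoef(ra, rb)[0, 1])


def tuning_shift_contrast(fits_by_condition: dict[str, list[STRFFit]]) -> np.ndarray:
    """Per-electrode partial-correlation shift

        delta_rho = rho(AFTER, MIDDLE | BEFORE) - rho(BEFORE, MIDDLE | AFTER).

    Each condition's eSTRF enters as its t-value map (the z-score of
    every spectrotemporal feature across jackknife folds), flattened in
    lag-major order.  The value is invariant to any fixed reordering of
    the features.
    """
    out = np.empty(len(fits_by_condition["middle"]))
    for i, (fb, fm, fa) in enumerate(
        zip(
            fits_by_condition["before"],
            fits_by_condition["middle"],
            fits_by_condition["after"],
        )
    ):
        b, m, a = fb.tmap.ravel(), fm.tmap.ravel(), fa.tmap.ravel()
        out[i] = partial_correlation(a, m, b) - partial_correlation(b, m, a)
    return out
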