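"""Auditory spectrogram: gammatone filterbank front end.

The encoding models take as input an "auditory spectrogram" S(t, p): the
amplitude envelope of the waveform in ERB-spaced gammatone bands between
180 and 7000 Hz, with half-wave rectification, power-law compression,
lateral-inhibition-style spectral sharpening and a leaky integrator
(8 ms time constant).  The 128 native bands are block-averaged to 32 and
the envelope is resampled to 50 Hz before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "AuditorySpectrogram",
    "erb_space",
    "gammatone_spectrogram",
    "reduce_bands",
    "resample_time",
    "reduce_and_resample",
    "N_BANDS_NATIVE",
    "N_BANDS_REDUCED",
    "default_band_centers",
]

N_BANDS_NATIVE = 128
N_BANDS_REDUCED = 32
FMIN = 180.0
FMAX = 7000.0
INTEGRATOR_TAU = 0.008  # s


@dataclass
class AuditorySpectrogram:
    """Time x band amplitude matrix with band centre frequencies.

    ``values`` is non-negative (before any later standardization);
    ``band_centers`` strictly increasing, in Hz; ``rate`` in Hz.
    """

    values: np.ndarray
    band_centers: np.ndarray
    rate: float

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.rate


def _erb_number(f: np.ndarray) -> np.ndarray:
    # Glasberg & Moore ERB-rate scale
    return 21.4 * np.log10(1.0 + 4.37e-3 * np.asarray(f, dtype=float))


def _erb_number_inv(e: np.ndarray) -> np.ndarray:
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 4.37e-3


def erb_space(fmin: float = FMIN, fmax: float = FMAX, n: int = N_BANDS_NATIVE) -> np.ndarray:
    """``n`` centre frequencies uniformly spaced on the ERB-rate scale."""
    return _erb_number_inv(np.linspace(_erb_number(fmin), _erb_number(fmax), n))


def default_band_centers(n: int = N_BANDS_REDUCED) -> np.ndarray:
    """Band centres of the reduced auditory spectrogram (geometric means
    of merged native bands)."""
    native = erb_space()
    block = N_BANDS_NATIVE // n
    return np.exp(np.log(native).reshape(n, block).mean(axis=1))


def gammatone_spectrogram(
    waveform: np.ndarray,
    audio_rate: float,
    n_bands: int = N_BANDS_NATIVE,
    compression_exponent: float = 1.0 / 3.0,
    sharpen: bool = True,
) -> AuditorySpectrogram:
    """Native-resolution auditory spectrogram at the audio rate.

    Per band: fourth-order gammatone filter, half-wave rectification,
    power-law compression (cube root by default), first-difference
    spectral sharpening across bands (clipped at zero), and a leaky
    integrator with an 8 ms time constant.

    Raises
    ------
    ValueError
        If ``audio_rate`` is below 14 kHz (2x the top band).
    """
    if audio_rate < 2 * FMAX:
        raise ValueError("audio_rate must be at least 14 kHz")
    x = np.asarray(waveform, dtype=float)
    centers = erb_space(n=n_bands)
    out = np.empty((x.size, n_bands))
    for i, fc in enumerate(centers):
        b, a = signal.gammatone(fc, "iir", fs=audio_rate)
        out[:, i] = signal.lfilter(b, a, x)
    np.maximum(out, 0.0, out=out)
    # flush values far below the signal scale: subnormal intermediates
    # make the elementwise chain pathologically slow on some CPUs
    peak = out.max()
    if peak > 0:
        out[out < 1e-12 * peak] = 0.0
    if compression_exponent == 1.0 / 3.0:
        np.cbrt(out, out=out)
    else:
        out **= compression_exponent
    if sharpen:
        sharp = np.empty_like(out)
        sharp[:, 0] = out[:, 0]
        sharp[:, 1:] = np.maximum(out[:, 1:] - out[:, :-1], 0.0)
        out = sharp
    alpha = np.exp(-1.0 / (INTEGRATOR_TAU * audio_rate))
    out = signal.lfilter([1.0 - alpha], [1.0, -alpha], out, axis=0)
    return AuditorySpectrogram(values=out, band_centers=centers, rate=audio_rate)


def reduce_bands(spec: AuditorySpectrogram, n_out: int = N_BANDS_REDUCED) -> AuditorySpectrogram:
    """Average blocks of adjacent bands; centres become geometric means.

    The number of input bands must be divisible by ``n_out``.  Block
    averaging conserves the total mean amplitude exactly.
    """
    n_in = spec.n_bands
    if n_in % n_out:
        raise ValueError(f"cannot reduce {n_in} bands to {n_out}: not divisible")
    block = n_in // n_out
    v = spec.values.reshape(spec.values.shape[0], n_out, block).mean(axis=2)
    centers = np.exp(np.log(spec.band_centers).reshape(n_out, block).mean(axis=1))
    return AuditorySpectrogram(values=v, band_centers=centers, rate=spec.rate)


def resample_time(spec: AuditorySpectrogram, target_rate: float = 50.0) -> AuditorySpectrogram:
    """Anti-alias low-pass (cutoff at the target Nyquist) and resample.

    Uses polyphase resampling; small negative overshoots from the
    anti-alias filter are clipped at zero so the amplitude stays
    non-negative.
    """
    frac = Fraction(target_rate / spec.rate).limit_denominator(10**6)
    v = signal.resample_poly(spec.values, frac.numerator, frac.denominator, axis=0, padtype="line")
    v = np.maximum(v, 0.0)
    return AuditorySpectrogram(values=v, band_centers=spec.band_centers, rate=target_rate)


def reduce_and_resample(
    spec: AuditorySpectrogram,
    n_out: int = N_BANDS_REDUCED,
    target_rate: float = 50.0,
) -> AuditorySpectrogram:
    """128 -> 32 band reduction followed by resampling to 50 Hz."""
    return resample_time(reduce_bands(spec, n_out=n_out), target_rate=target_rate)
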