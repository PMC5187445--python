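"""Modulation-domain stimulus processing.

A sound is represented as a Gaussian-windowed log-amplitude spectrogram.
The 2D Fourier transform of that (mean-removed) spectrogram lives in the
joint modulation domain: temporal modulations (Hz) on one axis and
spectral modulations (cycles/kHz) on the other; its amplitude is the
modulation power spectrum (MPS).  Filtered speech is made by zeroing a
region of the modulation domain (the modulation phase is untouched),
restoring the time-averaged spectral profile, and inverting the
spectrogram back to a waveform with an iterative phase-retrieval
algorithm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import gaussian

__all__ = [
    "Spectrogram",
    "ModulationSpectrum",
    "ModulationFilter",
    "compute_spectrogram",
    "compute_mps",
    "apply_modulation_filter",
    "invert_spectrogram",
    "synthesize_filtered_speech",
    "InversionResult",
]


@dataclass
class Spectrogram:
    """Log-amplitude spectrogram on uniform time and frequency grids.

    ``values`` is time x frequency in dB (20*log10 amplitude), clipped at
    ``max - floor_db``.  ``window_sigma`` is the Gaussian analysis-window
    standard deviation in seconds; ``time_step`` the hop in seconds.
    ``audio_rate`` and ``n_samples`` record the originating waveform so
    the spectrogram can be inverted on an identical grid.
    """

    values: np.ndarray
    freqs: np.ndarray
    time_step: float
    window_sigma: float
    floor_db: float
    audio_rate: float
    n_samples: int

    @property
    def freq_step(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.time_step

    def linear(self) -> np.ndarray:
        """Linear-amplitude values (undo the dB compression)."""
        return 10.0 ** (self.values / 20.0)


@dataclass
class ModulationSpectrum:
    """Complex 2D transform of a mean-removed log-spectrogram.

    Folded convention: spectral modulations ``wf >= 0`` (cycles/kHz) with
    signed temporal modulations ``wt`` (Hz).  The amplitude part is the
    MPS.  ``source_shape`` is the (time, freq) shape of the originating
    spectrogram, needed to state Parseval's identity on the folded grid.
    """

    complex_values: np.ndarray  # wt x wf
    wt: np.ndarray  # Hz, signed, ascending
    wf: np.ndarray  # cycles/kHz, >= 0
    source_shape: tuple[int, int]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_values)

    def fold_weights(self) -> np.ndarray:
        """Multiplicity of each wf column on the unfolded grid.

        Interior columns represent a conjugate pair; the DC column and
        (for even grids) the Nyquist column represent themselves only.
        """
        n_f = self.source_shape[1]
        w = np.full(self.complex_values.shape[1], 2.0)
        w[0] = 1.0
        if n_f % 2 == 0:
            w[-1] = 1.0
        return w

    def total_power(self) -> float:
        """Sum of |F|^2 over the full (unfolded) modulation grid."""
        return float(np.sum(self.fold_weights() * self.amplitude**2))


@dataclass
class ModulationFilter:
    """Low-pass modulation filter with a raised-cosine edge.

    ``kind='temporal_lowpass'`` removes temporal modulations above
    ``corner_temporal`` Hz; ``kind='spectral_lowpass'`` removes spectral
    modulations above ``corner_spectral`` cycles/kHz.  The transition is
    a raised cosine spanning ``transition_width`` (as a fraction of the
    corner) just above the corner; ``transition_width=0`` gives a brick
    wall.
    """

    kind: Literal["spectral_lowpass", "temporal_lowpass"]
    corner_spectral: float = 0.5
    corner_temporal: float = 3.0
    transition_width: float = 0.2

    def __post_init__(self) -> None:
        if self.kind not in ("spectral_lowpass", "temporal_lowpass"):
            raise ValueError(f"unknown filter kind: {self.kind!r}")
        corner = (
            self.corner_spectral
            if self.kind == "spectral_lowpass"
            else self.corner_temporal
        )
        if not corner > 0:
            raise ValueError("filter corner must be positive")
        if self.transition_width < 0:
            raise ValueError("transition_width must be >= 0")

    def gain(self, abs_freq: np.ndarray) -> np.ndarray:
        """Low-pass gain as a function of |modulation frequency|."""
        c = (
            self.corner_spectral
            if self.kind == "spectral_lowpass"
            else self.corner_temporal
        )
        a = np.abs(abs_freq)
        if self.transition_width == 0:
            return (a <= c).astype(float)
        edge = c * (1.0 + self.transition_width)
        g = np.zeros_like(a, dtype=float)
        g[a <= c] = 1.0
        trans = (a > c) & (a < edge)
        g[trans] = 0.5 * (1.0 + np.cos(np.pi * (a[trans] - c) / (edge - c)))
        return g


def _make_sft(audio_rate: float, window_sigma: float, time_step: float) -> ShortTimeFFT:
    """Build the ShortTimeFFT shared by analysis and inversion.

    The FFT length is chosen so the frequency step is close to
    1/(2*pi*sigma), the natural resolution of the Gaussian window.
    """
    hop = int(round(time_step * audio_rate))
    if hop < 1:
        raise ValueError("time_step too small for this audio rate")
    sig = window_sigma * audio_rate
    m = int(round(6 * sig))
    m += (m + 1) % 2  # odd length, +-3 sigma support
    mfft = int(round(2 * np.pi * sig))
    mfft = max(mfft + (mfft % 2), m + (m % 2))
    win = gaussian(m, std=sig, sym=True)
    return ShortTimeFFT(win, hop=hop, fs=audio_rate, mfft=mfft)


def compute_spectrogram(
    waveform: np.ndarray,
    audio_rate: float,
    window_sigma: float = 0.0071,
    time_step: float = 0.002,
    floor_db: float = 50.0,
) -> Spectrogram:
    """Gaussian-windowed log-amplitude spectrogram.

    Parameters
    ----------
    waveform : mono waveform.
    audio_rate : sampling rate in Hz.
    window_sigma : Gaussian window sigma in seconds (default 7.1 ms).
    time_step : hop in seconds (default 2 ms).
    floor_db : dynamic range; values are clipped at ``max - floor_db``.

    Raises
    ------
    ValueError
        If the waveform is shorter than six window sigmas.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if x.size < 6 * window_sigma * audio_rate:
        raise ValueError("waveform too short for the requested analysis window")
    sft = _make_sft(audio_rate, window_sigma, time_step)
    X = sft.stft(x)  # (freqs, frames)
    mag = np.abs(X).T  # time x freq
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag)
    db = np.maximum(db, db.max() - floor_db)
    freqs = sft.f
    return Spectrogram(
        values=db,
        freqs=np.asarray(freqs, dtype=float),
        time_step=sft.hop / audio_rate,
        window_sigma=window_sigma,
        floor_db=floor_db,
        audio_rate=audio_rate,
        n_samples=x.size,
    )


def compute_mps(spec: Spectrogram) -> ModulationSpectrum:
    """Modulation spectrum of a spectrogram.

    The grand mean of the log-spectrogram is removed before the 2D FFT,
    so the (0, 0) bin of the result is zero and all remaining power
    describes genuine modulation structure.  Axes: signed temporal
    modulation in Hz, non-negative spectral modulation in cycles/kHz.
    """
    v = spec.values - spec.values.mean()
    n_t, n_f = v.shape
    F = np.fft.fft2(v)
    n_keep = n_f // 2 + 1
    folded = np.fft.fftshift(F, axes=0)[:, :n_keep]
    wt = np.fft.fftshift(np.fft.fftfreq(n_t, d=spec.time_step))
    wf = np.fft.rfftfreq(n_f, d=spec.freq_step) * 1000.0  # cycles/kHz
    return ModulationSpectrum(
        complex_values=folded, wt=wt, wf=wf, source_shape=(n_t, n_f)
    )


def apply_modulation_filter(
    spec: Spectrogram,
    filt: ModulationFilter,
    restore_profile: bool = True,
) -> Spectrogram:
    """Filter a spectrogram in the modulation domain.

    The stop-band gain is set to zero (raised-cosine transition); the
    modulation phase is untouched in the pass band.  With
    ``restore_profile`` (default), the time-averaged spectral power
    profile is restored row-by-row afterwards, so the overall frequency
    power spectrum of the filtered sound matches the original — note
    this intentionally reinstates any *static* spectral structure (the
    ``wt = 0`` line), since a sound's long-term spectrum is exactly
    that; only time-varying modulations stay removed.  The per-row dB
    offsets are demeaned so the (0, 0) modulation component (the grand
    mean) is exactly preserved, leaving a single overall scale factor
    to be fixed at the waveform stage by RMS matching.
    """
    v = spec.values
    m = v.mean()
    c = v - m
    n_t, n_f = c.shape
    F = np.fft.fft2(c)
    if filt.kind == "temporal_lowpass":
        wt = np.fft.fftfreq(n_t, d=spec.time_step)
        mask = filt.gain(wt)[:, None]
    else:
        wf = np.fft.fftfreq(n_f, d=spec.freq_step) * 1000.0
        mask = filt.gain(wf)[None, :]
    cf = np.real(np.fft.ifft2(F * mask))
    vf = cf + m

    if restore_profile:
        # restore each frequency row's time-averaged linear power
        p_orig = np.mean(10.0 ** (v / 10.0), axis=0)
        p_new = np.mean(10.0 ** (vf / 10.0), axis=0)
        offset = 10.0 * np.log10(p_orig / p_new)
        offset -= offset.mean()  # keep the (0,0) modulation component intact
        vf = vf + offset[None, :]

    return Spectrogram(
        values=vf,
        freqs=spec.freqs,
        time_step=spec.time_step,
        window_sigma=spec.window_sigma,
        floor_db=spec.floor_db,
        audio_rate=spec.audio_rate,
        n_samples=spec.n_samples,
    )


class InversionResult(NamedTuple):
    waveform: np.ndarray
    rel_error: float
    n_iter_run: int


def invert_spectrogram(
    spec: Spectrogram,
    audio_rate: float | None = None,
    n_iter: int = 30,
    seed: int = 0,
) -> InversionResult:
    """Invert a magnitude spectrogram by iterative phase retrieval.

    Phases are initialized at random (seeded) and refined by
    alternating waveform reconstruction and magnitude replacement
    (Griffin-Lim).  The best iterate (smallest relative magnitude
    error) is returned.  If the error increases on three consecutive
    iterations a warning is issued and iteration stops.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if audio_rate is None:
        audio_rate = spec.audio_rate
    sft = _make_sft(audio_rate, spec.window_sigma, spec.time_step)
    # single precision: the iteration is magnitude-projection dominated
    # and float32 FFTs roughly halve the cost of the inner loop
    target = spec.linear().T.astype(np.float32)  # freqs x frames
    norm = np.linalg.norm(target)
    n = spec.n_samples

    rng = np.random.default_rng(seed)
    phase = rng.uniform(-np.pi, np.pi, size=target.shape).astype(np.float32)
    Z = (target * np.exp(1j * phase)).astype(np.complex64)

    best_x = None
    best_err = np.inf
    n_increase = 0
    prev_err = np.inf
    k = 0
    for k in range(1, n_iter + 1):
        x = sft.istft(Z, k1=n)
        X = sft.stft(x.astype(np.float32))
        if X.shape != target.shape:  # pragma: no cover - grid mismatch guard
            X = X[:, : target.shape[1]]
        mag = np.abs(X)
        err = float(np.linalg.norm(mag - target) / norm)
        if err < best_err:
            best_err = err
            best_x = x
        if err > prev_err:
            n_increase += 1
            if n_increase >= 3:
                warnings.warn(
                    "spectrogram inversion diverging; returning best iterate",
                    RuntimeWarning,
                )
                break
        else:
            n_increase = 0
        prev_err = err
        np.maximum(mag, np.float32(1e-12), out=mag)
        Z = target * (X / mag)
    return InversionResult(
        waveform=np.asarray(best_x, dtype=float), rel_error=best_err, n_iter_run=k
    )


def synthesize_filtered_speech(
    waveform: np.ndarray,
    audio_rate: float,
    filt: ModulationFilter,
    n_iter: int = 30,
    seed: int = 0,
    **spectrogram_kwargs,
) -> np.ndarray:
    """Modulation-filter a waveform: spectrogram -> filter -> invert.

    The output is trimmed/padded to the input length and scaled to the
    input RMS, so filtering changes the modulation content of the sound
    but not its overall level.
    """
    x = np.asarray(waveform, dtype=float)
    spec = compute_spectrogram(x, audio_rate, **spectrogram_kwargs)
    fspec = apply_modulation_filter(spec, filt)
    y = invert_spectrogram(fspec, audio_rate, n_iter=n_iter, seed=seed).waveform
    if y.size < x.size:
        y = np.pad(y, (0, x.size - y.size))
    else:
        y = y[: x.size]
    rms_in = np.sqrt(np.mean(x**2))
    rms_out = np.sqrt(np.mean(y**2))
    if rms_out > 0:
        y = y * (rms_in / rms_out)
    return y
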