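"""Synthetic filtered-speech experiments with known ground truth.

Emulates the three-condition passive-listening paradigm: each trial
presents a modulation-filtered sound (BEFORE), the unfiltered sound
(MIDDLE), and the identical filtered sound again (AFTER); no sound is
reused across trials.  Electrode responses are generated as the causal
convolution of a ground-truth STRF with the auditory spectrogram plus
noise.  Tuning plasticity is built in by construction: the AFTER
ground-truth STRF is shifted partway toward the MIDDLE truth,

    g_after = (1 - lambda) * g_before + lambda * g_middle,

so the shift coefficient ``lambda`` is the known effect size every
downstream contrast should detect (and should not detect at
``lambda = 0``).

Seed handling: one master seed; per-trial, per-electrode and per-noise
streams are derived from fixed integer key tuples, so any subset of the
experiment is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as _sig
from scipy.interpolate import interp1d

from strfshift import auditory, modulation
from strfshift.strf import DEFAULT_LAGS_S, build_lagged_design

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "StimulusSet",
    "TrialSet",
    "CONDITIONS",
    "generate_speech_like_sound",
    "generate_ground_truth_strfs",
    "simulate_hfb",
    "generate_stimulus_set",
    "generate_experiment",
    "simulate_responses",
]

CONDITIONS = ("before", "middle", "after")

N_LAGS = len(DEFAULT_LAGS_S)
N_BANDS = auditory.N_BANDS_REDUCED


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic experiment.

    ``shift_lambda`` interpolates the AFTER truth between the BEFORE
    truth (0) and the MIDDLE truth (1).  ``snr`` is the linear
    signal-to-noise variance ratio of the simulated HFB.  ``evoked_gain``
    adds a stimulus-energy-driven evoked component (a flat zero-lag
    filter, so it stays inside the linear model class) shared by all
    electrodes and conditions, mimicking the broad evoked HFB rise that
    real speech-responsive electrodes show.
    """

    n_trials: int = 20
    n_electrodes: int = 30
    audio_rate: float = 16000.0
    trial_duration: float = 3.0
    snr: float = 4.0
    shift_lambda: float = 0.8
    seed: int = 0
    filter_type: Literal["spectral_lowpass", "temporal_lowpass"] = "temporal_lowpass"
    noise_model: Literal["white", "ar1"] = "white"
    ar_coef: float = 0.7
    evoked_gain: float = 1.0
    n_gabor_components: int = 1
    pre_silence: float = 1.0
    post_silence: float = 0.2
    coherence_rate: float = 100.0
    inversion_iters: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.shift_lambda <= 1.0:
            raise ValueError("shift_lambda must be in [0, 1]")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials (jackknife folds)")
        if self.n_electrodes < 1:
            raise ValueError("need at least 1 electrode")

    def modulation_filter(self) -> modulation.ModulationFilter:
        return modulation.ModulationFilter(kind=self.filter_type)


@dataclass
class SyntheticTruth:
    """Ground-truth per-electrode STRFs per condition.

    Tensors are (n_electrodes, n_lags, n_bands), sharing the lag/band
    grid of the fitted models; ``strf_after`` is the exact elementwise
    lambda-interpolation of the other two.
    """

    strf_before: np.ndarray
    strf_middle: np.ndarray
    strf_after: np.ndarray
    shift_lambda: float
    snr: float
    seed: int


@dataclass
class StimulusSet:
    """Per-trial sounds and their auditory spectrograms.

    Spectrograms include ``pre_silence`` seconds of silence before
    onset (for baselining) and ``post_silence`` after offset; ``times*``
    give sample times relative to stimulus onset.
    """

    sounds: list[np.ndarray]
    filtered: list[np.ndarray]
    spec50_filtered: list[np.ndarray]
    spec50_unfiltered: list[np.ndarray]
    spec100_filtered: list[np.ndarray]
    spec100_unfiltered: list[np.ndarray]
    band_centers: np.ndarray
    times50: np.ndarray
    times100: np.ndarray
    audio_rate: float


@dataclass
class TrialSet:
    """Complete simulated experiment.

    ``hfb50`` / ``hfb100`` are (condition, trial, electrode, time) with
    condition order BEFORE, MIDDLE, AFTER.  BEFORE and AFTER share the
    same (bit-identical) filtered audio within a trial, per the task
    design.
    """

    config: SyntheticConfig
    stim: StimulusSet
    hfb50: np.ndarray
    hfb100: np.ndarray
    conditions: tuple[str, ...] = CONDITIONS

    @property
    def n_presentations(self) -> int:
        return len(self.conditions) * self.config.n_trials

    def audio(self, condition: str, trial: int) -> np.ndarray:
        """The waveform presented for one (condition, trial) pair."""
        if condition == "middle":
            return self.stim.sounds[trial]
        if condition in ("before", "after"):
            return self.stim.filtered[trial]
        raise KeyError(condition)

    def hfb_by_condition(self, rate: float = 50.0) -> dict[str, np.ndarray]:
        arr = self.hfb50 if rate == 50.0 else self.hfb100
        return {c: arr[i] for i, c in enumerate(self.conditions)}


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _slow_noise(n: int, rate: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise low-passed below ``cutoff`` Hz."""
    x = rng.standard_normal(n)
    sos = _sig.butter(2, cutoff, fs=rate, output="sos")
    y = _sig.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def generate_speech_like_sound(
    duration: float, audio_rate: float, seed: int
) -> np.ndarray:
    """A speech-like synthetic sound.

    A harmonic stack whose fundamental drifts between 90 and 250 Hz is
    shaped by 2-4 slowly moving formant-like spectral peaks, gated by a
    syllabic amplitude envelope (3-8 Hz), with brief broadband bursts
    standing in for plosives.  The modulation power of such a sound is
    concentrated at low temporal and spectral modulations, like real
    speech.  Peak amplitude is normalized to 0.9 full scale.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed, 101)
    n = int(round(duration * audio_rate))
    t = np.arange(n) / audio_rate

    # drifting fundamental: +-0.4 octave around a random centre
    f0_center = rng.uniform(110.0, 200.0)
    f0 = np.clip(f0_center * 2.0 ** (0.4 * _slow_noise(n, audio_rate, 1.5, rng)), 90.0, 250.0)
    phase = 2.0 * np.pi * np.cumsum(f0) / audio_rate

    # formant-like spectral peaks drifting slowly in log-frequency
    n_formants = int(rng.integers(2, 5))
    centers = np.sort(rng.uniform(np.log2(300.0), np.log2(3500.0), n_formants))
    drifts = [0.25 * _slow_noise(n, audio_rate, 0.8, rng) for _ in range(n_formants)]
    amps = rng.uniform(0.6, 1.0, n_formants)

    max_harmonic = int(7000.0 // 90.0)
    voiced = np.zeros(n)
    for k in range(1, max_harmonic + 1):
        fk = k * f0
        active = fk < 0.45 * audio_rate
        if not active.any():
            break
        logfk = np.log2(np.maximum(fk, 1.0))
        env = np.zeros(n)
        for c, d, a in zip(centers, drifts, amps):
            env += a * np.exp(-((logfk - (c + d)) ** 2) / (2.0 * 0.35**2))
        env += 0.02
        env *= 1.0 / (1.0 + (fk / 800.0))  # spectral tilt
        env[fk >= 7000.0] = 0.0
        voiced += env * np.sin(k * phase + rng.uniform(0, 2 * np.pi))

    # syllabic gating at 3-8 Hz with phase jitter
    syl_rate = rng.uniform(3.0, 8.0)
    syl_phase = 2.0 * np.pi * syl_rate * t + 0.8 * _slow_noise(n, audio_rate, 1.0, rng)
    syllable = np.maximum(np.sin(syl_phase), 0.0) ** 0.7 + 0.05
    x = voiced * syllable

    # brief broadband bursts at roughly 1.5 per second
    n_bursts = max(1, int(round(1.5 * duration)))
    burst_sos = _sig.butter(2, (1000.0, 7000.0), btype="bandpass", fs=audio_rate, output="sos")
    scale = np.std(x)
    for _ in range(n_bursts):
        width = int(rng.uniform(0.02, 0.04) * audio_rate)
        start = int(rng.uniform(0, max(n - width, 1)))
        burst = _sig.sosfilt(burst_sos, rng.standard_normal(width))
        burst *= np.hanning(width) * 0.6 * scale / max(burst.std(), 1e-12)
        x[start : start + width] += burst

    return 0.9 * x / np.max(np.abs(x))


def _gabor(
    rng: np.random.Generator,
    lags_s: np.ndarray,
    n_bands: int,
    n_components: int,
    f_tau_range: tuple[float, float] = (1.0, 8.0),
    f_band_range: tuple[float, float] = (0.02, 0.12),
) -> np.ndarray:
    """Random 2D Gabor (or Gabor mixture) on the lag x band grid, z-scored.

    ``f_tau_range`` (Hz) and ``f_band_range`` (cycles/band) bound the
    modulation carriers, i.e. where the filter's MTF concentrates.
    """
    tau = lags_s[:, None]
    band = np.arange(n_bands)[None, :]
    g = np.zeros((lags_s.size, n_bands))
    for _ in range(n_components):
        tau0 = rng.uniform(0.05, 0.25)
        band0 = rng.uniform(4, n_bands - 5)
        s_tau = rng.uniform(0.04, 0.09)
        s_band = rng.uniform(2.5, 5.0)
        f_tau = rng.uniform(*f_tau_range) * rng.choice([-1.0, 1.0])
        f_band = rng.uniform(*f_band_range) * rng.choice([-1.0, 1.0])
        phi = rng.uniform(0, 2 * np.pi)
        envelope = np.exp(
            -((tau - tau0) ** 2) / (2 * s_tau**2) - ((band - band0) ** 2) / (2 * s_band**2)
        )
        carrier = np.cos(2 * np.pi * (f_tau * (tau - tau0) + f_band * (band - band0)) + phi)
        g += envelope * carrier
    return (g - g.mean()) / g.std()


#: modulation-carrier ranges of the ground-truth Gabors.  The MIDDLE
#: (clean speech) truth concentrates at low temporal/spectral
#: modulations, where speech modulation power lives, emulating the
#: speech-matched tuning of clean-speech receptive fields; the BEFORE
#: truth spans a broader range.
MIDDLE_F_TAU = (0.5, 2.0)
MIDDLE_F_BAND = (0.01, 0.05)
BEFORE_F_TAU = (2.5, 6.0)
BEFORE_F_BAND = (0.04, 0.12)


def generate_ground_truth_strfs(config: SyntheticConfig) -> SyntheticTruth:
    """Random Gabor ground-truth STRFs with the AFTER truth interpolated.

    BEFORE and MIDDLE truths are independent standardized 2D Gabors per
    electrode (random centre band, best lag 50-250 ms, random sign);
    the MIDDLE truth's modulation carriers are drawn from the
    low-modulation range where speech power concentrates, so shifting
    toward it increases speech-feature overlap, as in the modelled
    experiment.  The AFTER truth is exactly
    ``(1 - lambda) * before + lambda * middle`` elementwise (no
    re-standardization, so the endpoint identities hold bit-exactly).
    """
    lam = config.shift_lambda
    before = np.empty((config.n_electrodes, N_LAGS, N_BANDS))
    middle = np.empty_like(before)
    for e in range(config.n_electrodes):
        before[e] = _gabor(
            _rng(config.seed, 201, e), DEFAULT_LAGS_S, N_BANDS,
            config.n_gabor_components, BEFORE_F_TAU, BEFORE_F_BAND,
        )
        middle[e] = _gabor(
            _rng(config.seed, 202, e), DEFAULT_LAGS_S, N_BANDS,
            config.n_gabor_components, MIDDLE_F_TAU, MIDDLE_F_BAND,
        )
    after = (1.0 - lam) * before + lam * middle
    return SyntheticTruth(
        strf_before=before,
        strf_middle=middle,
        strf_after=after,
        shift_lambda=lam,
        snr=config.snr,
        seed=config.seed,
    )


def _make_noise(
    n: int, var: float, rng: np.random.Generator, model: str, ar_coef: float
) -> np.ndarray:
    if var == 0:
        return np.zeros(n)
    if model == "white":
        return rng.normal(0.0, np.sqrt(var), n)
    if model == "ar1":
        innov_sd = np.sqrt(var * (1.0 - ar_coef**2))
        e = rng.normal(0.0, innov_sd, n)
        return _sig.lfilter([1.0], [1.0, -ar_coef], e)
    raise ValueError(f"unknown noise model: {model!r}")


def simulate_hfb(
    strf_true: np.ndarray,
    spectrogram: np.ndarray | auditory.AuditorySpectrogram,
    snr: float,
    seed: int = 0,
    rate: float = 50.0,
    noise_model: str = "white",
    ar_coef: float = 0.7,
) -> np.ndarray:
    """Simulated HFB trace: causal STRF convolution plus noise.

    ``r(t) = sum_tau sum_p g(tau, p) S(t - tau, p) + eps(t)`` with the
    gain tensor's rows taken as consecutive-sample lags at ``rate``, and
    white (or AR(1)) Gaussian noise scaled so var(signal)/var(eps)
    equals ``snr`` (``snr=inf`` for noiseless).
    """
    if isinstance(spectrogram, auditory.AuditorySpectrogram):
        S, rate = spectrogram.values, spectrogram.rate
    else:
        S = np.asarray(spectrogram, dtype=float)
    g = np.asarray(strf_true, dtype=float)
    if g.shape[1] != S.shape[1]:
        raise ValueError(
            f"band axis mismatch: STRF has {g.shape[1]} bands, spectrogram {S.shape[1]}"
        )
    lags_s = np.arange(g.shape[0]) / rate
    sig = build_lagged_design(S, lags_s, rate) @ g.ravel()
    if np.isinf(snr):
        return sig
    var_noise = sig.var() / snr
    rng = np.random.default_rng(seed)
    return sig + _make_noise(sig.size, var_noise, rng, noise_model, ar_coef)


def _padded_spectrograms(
    sound: np.ndarray, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Silence-padded auditory spectrograms at 50 and 100 Hz."""
    fs = config.audio_rate
    padded = np.concatenate(
        [
            np.zeros(int(round(config.pre_silence * fs))),
            sound,
            np.zeros(int(round(config.post_silence * fs))),
        ]
    )
    native = auditory.gammatone_spectrogram(padded, fs)
    reduced = auditory.reduce_bands(native)
    s50 = auditory.resample_time(reduced, 50.0)
    s100 = auditory.resample_time(reduced, config.coherence_rate)
    return s50.values, s100.values, reduced.band_centers


def generate_stimulus_set(config: SyntheticConfig) -> StimulusSet:
    """Per-trial sounds, their modulation-filtered versions, and
    auditory spectrograms at the model (50 Hz) and coherence (100 Hz)
    rates.

    Generating the stimuli separately from the responses lets several
    shift coefficients be simulated on identical audio (as when
    sweeping ``shift_lambda``), since the stimuli depend only on the
    seed, not on lambda or snr.
    """
    filt = config.modulation_filter()
    sounds, filtered = [], []
    s50f, s50u, s100f, s100u = [], [], [], []
    band_centers = None
    for i in range(config.n_trials):
        sound_seed = int(_rng(config.seed, 301, i).integers(0, 2**31 - 1))
        x = generate_speech_like_sound(config.trial_duration, config.audio_rate, sound_seed)
        y = modulation.synthesize_filtered_speech(
            x, config.audio_rate, filt, n_iter=config.inversion_iters, seed=sound_seed
        )
        sounds.append(x)
        filtered.append(y)
        a50, a100, band_centers = _padded_spectrograms(x, config)
        b50, b100, _ = _padded_spectrograms(y, config)
        s50u.append(a50)
        s100u.append(a100)
        s50f.append(b50)
        s100f.append(b100)
    t50 = np.arange(s50u[0].shape[0]) / 50.0 - config.pre_silence
    t100 = np.arange(s100u[0].shape[0]) / config.coherence_rate - config.pre_silence
    return StimulusSet(
        sounds=sounds,
        filtered=filtered,
        spec50_filtered=s50f,
        spec50_unfiltered=s50u,
        spec100_filtered=s100f,
        spec100_unfiltered=s100u,
        band_centers=band_centers,
        times50=t50,
        times100=t100,
        audio_rate=config.audio_rate,
    )


def _interp_lags(truth: np.ndarray, rate: float) -> np.ndarray:
    """Resample the truth lag axis (20 ms grid) to consecutive samples
    at ``rate``."""
    if rate == 50.0:
        return truth
    new_lags = np.arange(0.0, DEFAULT_LAGS_S[-1] + 0.5 / rate, 1.0 / rate)
    f = interp1d(DEFAULT_LAGS_S, truth, axis=1, fill_value=0.0, bounds_error=False)
    return f(new_lags)


def simulate_responses(
    stim: StimulusSet, truth: SyntheticTruth, config: SyntheticConfig
) -> TrialSet:
    """Simulate HFB for every (condition, trial, electrode).

    BEFORE and AFTER use the filtered-sound spectrograms with their
    respective truth tensors; MIDDLE uses the unfiltered sound with the
    MIDDLE truth.  An evoked component proportional to overall stimulus
    energy is shared by all electrodes; independent noise is drawn per
    (condition, trial, electrode) at the configured SNR.
    """
    truth_by_cond = {
        "before": truth.strf_before,
        "middle": truth.strf_middle,
        "after": truth.strf_after,
    }
    out = {}
    for rate, spec_f, spec_u in (
        (50.0, stim.spec50_filtered, stim.spec50_unfiltered),
        (config.coherence_rate, stim.spec100_filtered, stim.spec100_unfiltered),
    ):
        n_t = spec_f[0].shape[0]
        hfb = np.empty((3, config.n_trials, config.n_electrodes, n_t))
        g_cond = {
            c: _interp_lags(g, rate).reshape(config.n_electrodes, -1).T
            for c, g in truth_by_cond.items()
        }  # (D, E)
        lags_s = np.arange(g_cond["before"].shape[0] // N_BANDS) / rate
        for i in range(config.n_trials):
            for ci, cond in enumerate(CONDITIONS):
                S = spec_u[i] if cond == "middle" else spec_f[i]
                X = build_lagged_design(S, lags_s, rate)
                sig = X @ g_cond[cond]  # (T, E)
                # snr is defined against the feature-driven signal; the
                # evoked component is an additional deterministic part
                var_noise = (
                    sig.var(axis=0) / config.snr
                    if np.isfinite(config.snr)
                    else np.zeros(config.n_electrodes)
                )
                env = S.mean(axis=1)
                env_sd = env.std()
                sig_scale = sig.std(axis=0).mean()
                if config.evoked_gain > 0 and env_sd > 0:
                    sig = sig + (config.evoked_gain * sig_scale / env_sd) * env[:, None]
                for e in range(config.n_electrodes):
                    rng = _rng(config.seed, 401, int(rate), ci, i, e)
                    noise = _make_noise(n_t, var_noise[e], rng, config.noise_model, config.ar_coef)
                    hfb[ci, i, e] = sig[:, e] + noise
        out[rate] = hfb
    return TrialSet(
        config=config,
        stim=stim,
        hfb50=out[50.0],
        hfb100=out[config.coherence_rate],
    )


def generate_experiment(config: SyntheticConfig) -> tuple[TrialSet, SyntheticTruth]:
    """Generate a complete synthetic experiment.

    Deterministic given the config (including the seed): stimuli,
    ground-truth STRFs, and simulated responses.
    """
    stim = generate_stimulus_set(config)
    truth = generate_ground_truth_strfs(config)
    return simulate_responses(stim, truth, config), truth
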