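"""File I/O: WAV waveforms and the HDF5 trial-set container.

HDF5 layout (one file per experiment)::

    /audio/unfiltered_<i>      float32, mono waveform of trial i
    /audio/filtered_<i>        float32, its modulation-filtered version
                               (presented in both BEFORE and AFTER)
    /spectrograms/filtered50_<i>, unfiltered50_<i>,
                  filtered100_<i>, unfiltered100_<i>
    /spectrograms/band_centers
    /hfb/values50              (condition, trial, electrode, time), 50 Hz
    /hfb/values100             same at the coherence rate
    /hfb/times50, /hfb/times100   seconds relative to stimulus onset
    /conditions                condition order (bytes)
    /truth/before, /truth/middle, /truth/after
                               (electrode, lag, band) ground-truth STRFs
    root attrs                 the SyntheticConfig fields

All arrays are plain datasets; the layout is self-describing enough to
be read without this package.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from strfshift.synthetic import (
    StimulusSet,
    SyntheticConfig,
    SyntheticTruth,
    TrialSet,
)

__all__ = ["write_wav", "read_wav", "save_trialset", "load_trialset"]


def write_wav(path: str | Path, waveform: np.ndarray, rate: float) -> None:
    """Write a mono float waveform as 16-bit PCM WAV (clipped at +-1)."""
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(rate), (x * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file, returning (float waveform in [-1, 1], rate)."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=float), float(rate)


def save_trialset(path: str | Path, trialset: TrialSet, truth: SyntheticTruth) -> None:
    """Serialize a TrialSet and its ground truth to HDF5."""
    cfg = trialset.config
    stim = trialset.stim
    with h5py.File(str(path), "w") as f:
        for key, val in asdict(cfg).items():
            f.attrs[key] = val
        audio = f.create_group("audio")
        specs = f.create_group("spectrograms")
        for i in range(cfg.n_trials):
            audio.create_dataset(f"unfiltered_{i}", data=stim.sounds[i].astype(np.float32))
            audio.create_dataset(f"filtered_{i}", data=stim.filtered[i].astype(np.float32))
            specs.create_dataset(f"filtered50_{i}", data=stim.spec50_filtered[i])
            specs.create_dataset(f"unfiltered50_{i}", data=stim.spec50_unfiltered[i])
            specs.create_dataset(f"filtered100_{i}", data=stim.spec100_filtered[i])
            specs.create_dataset(f"unfiltered100_{i}", data=stim.spec100_unfiltered[i])
        specs.create_dataset("band_centers", data=stim.band_centers)
        hfb = f.create_group("hfb")
        hfb.create_dataset("values50", data=trialset.hfb50)
        hfb.create_dataset("values100", data=trialset.hfb100)
        hfb.create_dataset("times50", data=stim.times50)
        hfb.create_dataset("times100", data=stim.times100)
        f.create_dataset("conditions", data=np.array([c.encode() for c in trialset.conditions]))
        tg = f.create_group("truth")
        tg.create_dataset("before", data=truth.strf_before)
        tg.create_dataset("middle", data=truth.strf_middle)
        tg.create_dataset("after", data=truth.strf_after)


def load_trialset(path: str | Path) -> tuple[TrialSet, SyntheticTruth]:
    """Load a TrialSet and ground truth previously written by
    :func:`save_trialset`."""
    with h5py.File(str(path), "r") as f:
        cfg = SyntheticConfig(**{k: f.attrs[k] for k in SyntheticConfig.__dataclass_fields__})
        n = cfg.n_trials
        stim = StimulusSet(
            sounds=[f[f"audio/unfiltered_{i}"][...].astype(float) for i in range(n)],
            filtered=[f[f"audio/filtered_{i}"][...].astype(float) for i in range(n)],
            spec50_filtered=[f[f"spectrograms/filtered50_{i}"][...] for i in range(n)],
            spec50_unfiltered=[f[f"spectrograms/unfiltered50_{i}"][...] for i in range(n)],
            spec100_filtered=[f[f"spectrograms/filtered100_{i}"][...] for i in range(n)],
            spec100_unfiltered=[f[f"spectrograms/unfiltered100_{i}"][...] for i in range(n)],
            band_centers=f["spectrograms/band_centers"][...],
            times50=f["hfb/times50"][...],
            times100=f["hfb/times100"][...],
            audio_rate=cfg.audio_rate,
        )
        trialset = TrialSet(
            config=cfg,
            stim=stim,
            hfb50=f["hfb/values50"][...],
            hfb100=f["hfb/values100"][...],
            conditions=tuple(c.decode() for c in f["conditions"][...]),
        )
        truth = SyntheticTruth(
            strf_before=f["truth/before"][...],
            strf_middle=f["truth/middle"][...],
            strf_after=f["truth/after"][...],
            shift_lambda=float(f.attrs["shift_lambda"]),
            snr=float(f.attrs["snr"]),
            seed=int(f.attrs["seed"]),
        )
    return trialset, truth
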