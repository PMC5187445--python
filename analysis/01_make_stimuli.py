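"""Synthesize speech-like sounds and their modulation-filtered versions.

Generates a handful of stimuli, applies the spectral (0.5 cycles/kHz)
and temporal (3 Hz) low-pass modulation filters, and verifies the two
properties the stimulus arm is built around: the sounds' modulation
power concentrates at low modulations (like speech), and filtering
removes the targeted modulations while preserving the overall level.

Writes results/stimulus_properties.csv and example WAVs under
results/stimuli/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from strfshift import io as sio
from strfshift import modulation as M
from strfshift import synthetic as SY

OUT = Path(__file__).resolve().parents[1] / "results"
FS = 16000.0
N_SOUNDS = 4


def mps_low_fraction(mps):
    power = mps.amplitude**2 * mps.fold_weights()
    dc = (np.abs(mps.wt[:, None]) < 1e-9) & (mps.wf[None, :] < 1e-9)
    low = (np.abs(mps.wt[:, None]) < 10.0) & (mps.wf[None, :] < 3.0) & ~dc
    total = power.sum() - power[dc].sum()
    return power[low].sum() / total


def stopband_fraction(mps, filt):
    power = mps.amplitude**2 * mps.fold_weights()
    if filt.kind == "temporal_lowpass":
        stop = np.abs(mps.wt[:, None]) > filt.corner_temporal * 1.2
    else:
        stop = mps.wf[None, :] > filt.corner_spectral * 1.2
    stop = stop & np.ones_like(power, bool)
    return power[stop].sum() / power.sum()


def main():
    (OUT / "stimuli").mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(N_SOUNDS):
        x = SY.generate_speech_like_sound(2.5, FS, seed=100 + i)
        spec = M.compute_spectrogram(x, FS)
        mps = M.compute_mps(spec)
        row = {"sound": i, "low_mod_fraction": mps_low_fraction(mps)}
        sio.write_wav(OUT / "stimuli" / f"sound_{i}_unfiltered.wav", x, FS)
        for kind, tag in (("temporal_lowpass", "temporal"), ("spectral_lowpass", "spectral")):
            filt = M.ModulationFilter(kind)
            y = M.synthesize_filtered_speech(x, FS, filt, seed=100 + i)
            sio.write_wav(OUT / "stimuli" / f"sound_{i}_{tag}.wav", y, FS)
            mps_f = M.compute_mps(M.compute_spectrogram(y, FS))
            row[f"stopband_fraction_{tag}_before"] = stopband_fraction(mps, filt)
            row[f"stopband_fraction_{tag}_after"] = stopband_fraction(mps_f, filt)
            row[f"rms_ratio_{tag}"] = np.sqrt(np.mean(y**2) / np.mean(x**2))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "stimulus_properties.csv", index=False)
    print(df.round(4).to_string(index=False))
    print(
        f"\nlow-modulation power fraction: {df.low_mod_fraction.mean():.2f} "
        "(speech concentrates its modulation power in this low-modulation "
        "region; individual sounds vary with their harmonic content)"
    )
    print(
        "temporal-filter stop-band power fraction before -> after: "
        f"{df.stopband_fraction_temporal_before.mean():.3f} -> "
        f"{df.stopband_fraction_temporal_after.mean():.3f}"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
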