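"""Generate the synthetic three-condition experiment used downstream.

Builds the main-effect experiment (25 trials x 3 s, 30 electrodes,
single-trial SNR 4, shift coefficient 0.8): per trial one unique
speech-like sound, its temporally modulation-filtered version presented
in BEFORE and AFTER, the unfiltered version in MIDDLE, and per-electrode
HFB simulated from condition-specific ground-truth STRFs.  Saves the
experiment container (HDF5) under scratch/ for the later scripts and a
small summary under results/.
"""

import sys
from pathlib import Path

from strfshift import experiments as EX
from strfshift import io as sio
from strfshift import synthetic as SY

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main():
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    cfg = SY.SyntheticConfig(seed=SEED, shift_lambda=0.8, **EX.HEADLINE_CONFIG)
    print(f"generating {cfg.n_trials} trials x {cfg.n_electrodes} electrodes "
          f"({cfg.trial_duration:.0f} s each, shift lambda={cfg.shift_lambda}) ...")
    trialset, truth = SY.generate_experiment(cfg)
    path = ROOT / "scratch" / "experiment_lambda08.h5"
    sio.save_trialset(path, trialset, truth)
    print(f"saved {path}")
    print(f"presentations: {trialset.n_presentations} "
          f"({len(trialset.conditions)} conditions x {cfg.n_trials} trials)")
    print(f"HFB arrays: 50 Hz {trialset.hfb50.shape}, "
          f"{cfg.coherence_rate:.0f} Hz {trialset.hfb100.shape}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
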