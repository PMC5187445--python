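"""Quantify the tuning shift: the full contrast battery plus statistics.

Runs the complete downstream analysis on the saved experiment and
reports the four tuning-shift contrasts over selected electrodes:

* delta rho   — partial-correlation shift of the eSTRF toward the
                clean-speech eSTRF,
* delta RMS   — output power of the filtered-speech eSTRFs driven by
                clean speech (matched-filter overlap),
* delta R^2   — generalization of clean-speech coefficients to the
                filtered conditions,
* delta MI    — between-condition response similarity in bits/s,

each with its sign-flip permutation p-value, plus the cluster-based
permutation test on the AFTER-BEFORE evoked HFB time course.

Writes results/tuning_contrasts.csv and results/report/ (full report).
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from strfshift import io as sio
from strfshift import pipeline as PL

ROOT = Path(__file__).resolve().parents[1]


def main():
    path = ROOT / "scratch" / "experiment_lambda08.h5"
    if not path.exists():
        print("run analysis/02_simulate_experiment.py first", file=sys.stderr)
        return 1
    trialset, truth = sio.load_trialset(path)
    cfg = PL.RunConfig(
        synthetic_config=trialset.config, n_perm=10000, n_boot=10000,
        out_dir=str(ROOT / "results" / "report"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = PL.run_pipeline(cfg, data=(trialset, truth))

    print("\n".join(res.summary_lines))
    rows = []
    for name in ("delta_rho", "delta_rms", "delta_r2", "delta_mi"):
        c = res.contrasts[name]
        t = res.tests[name]
        rows.append({
            "contrast": name,
            "n_electrodes": len(c),
            "mean": t.observed,
            "se": c.std(ddof=1) / np.sqrt(len(c)),
            "fraction_positive": float(np.mean(c > 0)),
            "p_signflip": t.p_two_sided,
        })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "results" / "tuning_contrasts.csv", index=False)
    print("\nWith the built-in shift (lambda = 0.8), every contrast should be "
          "positive and significant: the AFTER receptive fields moved toward "
          "the clean-speech tuning and extract more speech-like structure.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
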