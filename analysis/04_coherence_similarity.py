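"""Between-condition response similarity in bits per second.

For every selected electrode, computes the sliding-window multitaper
coherence between each filtered-speech response (BEFORE, AFTER) and the
clean-speech response (MIDDLE) of the same trial, converts it to a
normal mutual-information rate, and tests the contrast
MI(AFTER/MIDDLE) - MI(BEFORE/MIDDLE) with and without removal of the
across-trial mean response (the global evoked component).

Writes results/coherence_contrast.csv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from strfshift import io as sio
from strfshift import pipeline as PL
from strfshift import stats

ROOT = Path(__file__).resolve().parents[1]


def main():
    path = ROOT / "scratch" / "experiment_lambda08.h5"
    if not path.exists():
        print("run analysis/02_simulate_experiment.py first", file=sys.stderr)
        return 1
    trialset, truth = sio.load_trialset(path)
    cfg = PL.RunConfig(
        synthetic_config=trialset.config, n_perm=10000, n_boot=5000,
        run_tuning=False, run_stats=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = PL.run_pipeline(cfg, data=(trialset, truth))

    rows = []
    for label in ("raw", "global_subtracted"):
        c = res.contrasts[f"mi_{label}"]
        test = stats.signflip_permutation_test(c["delta_mi"], n_perm=10000, seed=11)
        se = c["delta_mi"].std(ddof=1) / np.sqrt(len(c["delta_mi"]))
        rows.append({
            "variant": label,
            "n_electrodes": len(c["delta_mi"]),
            "delta_mi_mean_bits_per_s": test.observed,
            "delta_mi_se": se,
            "p_signflip": test.p_two_sided,
            **{f"group_{g}": np.nanmean(v) for g, v in c["group_means"].items()},
        })
        print(f"{label:18s}: delta MI = {test.observed:+.3f} +- {se:.3f} bits/s, "
              f"sign-flip p = {test.p_two_sided:.2g}")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "coherence_contrast.csv", index=False)
    print("\nA positive contrast that survives global-response subtraction means "
          "the AFTER response tracks sentence-specific temporal detail shared "
          "with the clean-speech response, not just an overall gain change.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
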