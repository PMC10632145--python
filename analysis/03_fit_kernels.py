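"""Fit signal-propagation kernels for the WT recordings, then characterize
their rise times (after desaturation) and the trial-to-trial stereotypy of
each connection.

Writes results/kernels_WT.csv with one row per fitted chain plus per-pair
rise time, and results/stereotypy_WT.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sigprop.kernels import rise_time, stereotypy
from sigprop.pipeline import average_kernels, fit_pair_kernels
from sigprop.screen import ClassifierThresholds
from sigprop.synth import Recording

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"
RESULTS = Path(__file__).resolve().parents[1] / "results"
THRESHOLDS = ClassifierThresholds(amp_thresh=0.05, deriv_thresh=0.001)


def main() -> None:
    recs = [Recording.load(p, RESULTS / "data" / f"{p.stem}_stimlog.csv")
            for p in sorted(SCRATCH.glob("WT_rec*.h5"))]
    trial_kernels = fit_pair_kernels(recs, THRESHOLDS, max_trials_per_pair=3)
    dt = recs[0].dt

    rows, stereo_rows = [], []
    t_stim = np.arange(0, 30, dt)
    stim = np.exp(-t_stim / 8.0) - np.exp(-t_stim / 1.5)
    for (j, i), trials in sorted(trial_kernels.items()):
        nonzero = [k for k in trials if not k.is_zero()]
        if not nonzero:
            continue
        avg = average_kernels(nonzero)
        rt = rise_time(avg)
        for ci, ch in enumerate(avg.chains):
            rows.append((j, i, len(nonzero), ci, ch.c, *ch.rates,
                         *([np.nan] * (3 - len(ch.rates))), rt))
        if len(nonzero) >= 2:
            stereo_rows.append((j, i, len(nonzero),
                                stereotypy(nonzero, [stim], dt)))

    kern = pd.DataFrame(rows, columns=["stim", "down", "n_trials", "chain",
                                       "c", "rate0", "rate1", "rate2",
                                       "rise_time_s"])
    kern.to_csv(RESULTS / "kernels_WT.csv", index=False)
    st = pd.DataFrame(stereo_rows, columns=["stim", "down", "n_trials",
                                            "stereotypy"])
    st.to_csv(RESULTS / "stereotypy_WT.csv", index=False)

    per_pair = kern.groupby(["stim", "down"])["rise_time_s"].first()
    print(f"fitted kernels for {per_pair.size} pairs "
          f"({(per_pair == 0).mean():.0%} with instantaneous rise after "
          f"desaturation; median rise {per_pair.median():.2f} s)")
    if len(st):
        print(f"stereotypy over {len(st)} pairs with >=2 trials: "
              f"median {st['stereotypy'].median():.3f} "
              f"(consistent connections score near 1)")


if __name__ == "__main__":
    main()
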