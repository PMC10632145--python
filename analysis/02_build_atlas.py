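"""Build the functional-connectivity atlas for each strain.

Loads the recordings written by 01_simulate_data.py, preprocesses the traces,
applies the autoresponse inclusion criteria, builds the empirical null from
the control recordings, and computes the per-pair statistics
(KS -> Fisher -> Storey q; TOST -> q_eq) and labels. Atlas tables go to
results/atlas_<strain>.csv.
"""

from pathlib import Path

from sigprop.pipeline import atlas_table
from sigprop.screen import ClassifierThresholds, apply_inclusion
from sigprop.stats import build_null, collect_pairs, compute_pair_stats
from sigprop.synth import Recording, SimConfig

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"
RESULTS = Path(__file__).resolve().parents[1] / "results"

# a small multiple of the recordings' dF/F0 noise floor (0.02 per sample)
THRESHOLDS = ClassifierThresholds(amp_thresh=0.05, deriv_thresh=0.001)


def build_for_strain(strain: str) -> list:
    recs = [Recording.load(p, p.parent.parent.parent / "results" / "data" / f"{p.stem}_stimlog.csv")
            for p in sorted(SCRATCH.glob(f"{strain}_rec*.h5"))]
    ctrls = [Recording.load(p) for p in sorted(SCRATCH.glob(f"{strain}_ctrl*.h5"))]
    null = build_null(ctrls, SimConfig())
    observations = []
    for rec in recs:
        observations.extend(apply_inclusion(rec, THRESHOLDS))
    pairs = collect_pairs(observations)
    stats = compute_pair_stats(pairs, null)
    atlas_table(stats).to_csv(RESULTS / f"atlas_{strain}.csv", index=False)
    n_conn = sum(s.label == "connected" for s in stats)
    n_non = sum(s.label == "non_connected" for s in stats)
    print(f"{strain}: {len(stats)} measured pairs -> {n_conn} connected, "
          f"{n_non} non-connected, {len(stats) - n_conn - n_non} undetermined "
          f"(null: {null.amp_samples.size} pseudo-windows, "
          f"sigma_amp={null.sigma_amp:.4f})")
    return stats


def main() -> None:
    for strain in ("WT", "unc-31"):
        build_for_strain(strain)


if __name__ == "__main__":
    main()
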