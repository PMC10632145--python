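"""Generate the synthetic study data: WT-like and unc-31-like stimulation
recordings, no-stimulation controls, and the matched connectome.

The WT network contains extrasynaptic (non-wired) functional edges; the
unc-31-like dataset uses the same network with those edges silenced and the
shorter 0.3-s stimulus. Raw trace containers (HDF5) go to scratch/, the
stimulation logs and connectome edge list to results/data.
"""

from pathlib import Path

import numpy as np

from sigprop.synth import (SimConfig, gen_connectome, gen_ground_truth,
                           knockout_extrasynaptic, simulate_control,
                           simulate_recording)

SEED = 1
N_NEURONS = 16
EDGE_DENSITY = 0.15
FRAC_EXTRASYNAPTIC = 0.2
N_RECORDINGS = 6
N_CONTROLS = 3
DURATION = 630.0
NOISE_SD = 2.0  # dF/F0 noise floor = NOISE_SD / baseline = 0.02 per sample
SPONT_RATE = 1 / 120.0  # tonic background transients per neuron per second

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "data"
RESULTS = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    net = gen_ground_truth(N_NEURONS, EDGE_DENSITY, frac_inhibitory=0.11,
                           frac_extrasynaptic=FRAC_EXTRASYNAPTIC, seed=SEED)
    mut_net = knockout_extrasynaptic(net)
    conn = gen_connectome(net, extra_anatomy_edges=2, seed=SEED + 1)
    conn.to_csv(RESULTS / "connectome.csv")

    n_extra = sum(net.extrasynaptic_flags.values())
    print(f"ground truth: {len(net.edges)} functional edges "
          f"({n_extra} extrasynaptic, absent from the wiring), "
          f"{int((conn.chem > 0).sum())} wired edges")

    rng = np.random.default_rng(SEED)
    for strain, network, stim_dur in (("WT", net, 0.5), ("unc-31", mut_net, 0.3)):
        for r in range(N_RECORDINGS):
            cfg = SimConfig(duration=DURATION, noise_sd=NOISE_SD,
                            stim_duration=stim_dur, strain=strain,
                            missing_fraction=0.02, response_probability=1.0,
                            spont_rate=SPONT_RATE,
                            seed=int(rng.integers(2**31)))
            rec = simulate_recording(network, cfg)
            tag = f"{strain}_rec{r}"
            rec.save(SCRATCH / f"{tag}.h5", RESULTS / f"{tag}_stimlog.csv")
        for r in range(N_CONTROLS):
            cfg = SimConfig(duration=DURATION, noise_sd=NOISE_SD, strain=strain,
                            missing_fraction=0.02, spont_rate=SPONT_RATE,
                            seed=int(rng.integers(2**31)))
            simulate_control(network, cfg).save(SCRATCH / f"{strain}_ctrl{r}.h5")
        print(f"{strain}: {N_RECORDINGS} stimulation recordings "
              f"({DURATION:.0f} s, {int(DURATION // 30)} stimuli each) "
              f"+ {N_CONTROLS} controls written")


if __name__ == "__main__":
    main()
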