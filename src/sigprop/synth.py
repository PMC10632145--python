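"""Synthetic stimulation-response recordings with known ground truth.

Emulates the structure of whole-brain single-neuron-stimulation calcium
imaging: a random neuron is targeted every 30 s with a short (0.3-0.5 s)
stimulus; the targeted neuron produces an autoresponse transient; downstream
neurons respond through ground-truth propagation kernels, unreliably from
trial to trial; traces carry double-exponential photobleaching, additive
Gaussian noise and missing samples.  Control recordings use the identical
generative model with an empty stimulation log and supply the empirical null
for the connectivity statistics.  A matched connectome can be generated in
which functionally "extrasynaptic" edges are deliberately absent from the
wiring, mimicking dense-core-vesicle-mediated signalling invisible to anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .anatomy import Connectome
from .kernels import Kernel, apply_kernel, random_kernel


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and generative parameters of a synthetic recording.

    dt is seconds per sample (0.5 s = 2 volumes/s); stimuli arrive every
    ``isi`` seconds; ``stim_duration`` is 0.5 s for WT-like and 0.3 s for
    unc-31-like recordings; ``bleach`` holds (a1, rate1, a2, rate2) of the
    multiplicative double-exponential decay (amplitudes sum to the t=0 gain);
    ``response_probability`` is the per-edge per-trial reliability.
    """

    dt: float = 0.5
    duration: float = 600.0
    isi: float = 30.0
    stim_duration: float = 0.5
    noise_sd: float = 1.0
    bleach: tuple[float, float, float, float] = (0.0, 1 / 300.0, 0.0, 1 / 60.0)
    missing_fraction: float = 0.0
    response_probability: float = 1.0
    autoresponse_peak: float = 1.0
    baseline: float = 100.0
    spont_rate: float = 0.0     # spontaneous transients per neuron per second
    spont_amp: float = 0.3      # mean peak dF/F0 of spontaneous transients
    seed: int = 0
    strain: str = "WT"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.isi < 30.0:
            raise ValueError("isi must cover the post-stimulus window (>= 30 s)")
        if not 0.0 <= self.missing_fraction < 0.5:
            raise ValueError("missing_fraction must be in [0, 0.5)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def n_stimuli(self) -> int:
        return int(self.duration // self.isi)


@dataclass
class Recording:
    """Raw fluorescence traces + stimulation log + strain label."""

    F: np.ndarray                 # time x neuron
    mask: np.ndarray              # True where the sample is missing
    dt: float
    stim_log: pd.DataFrame        # columns: time_s, target_index, duration_s, on_target
    strain: str = "WT"
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(self.F.shape[1])]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.F.shape[0]) * self.dt

    def save(self, traces_path, log_path=None) -> None:
        """Write traces to an HDF5 container and the stimulation log to CSV."""
        with h5py.File(traces_path, "w") as f:
            f.create_dataset("traces", data=self.F)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset("time", data=self.time)
            f.attrs["dt"] = self.dt
            f.attrs["strain"] = self.strain
        if log_path is not None:
            self.stim_log.to_csv(log_path, index=False)

    @classmethod
    def load(cls, traces_path, log_path=None) -> "Recording":
        with h5py.File(traces_path, "r") as f:
            F = f["traces"][:]
            mask = f["mask"][:].astype(bool)
            dt = float(f.attrs["dt"])
            strain = str(f.attrs["strain"])
        if log_path is not None:
            log = pd.read_csv(log_path)
        else:
            log = _empty_log()
        return cls(F=F, mask=mask, dt=dt, stim_log=log, strain=strain)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["time_s", "target_index", "duration_s", "on_target"])


@dataclass
class GroundTruthNetwork:
    """Known functional network behind a synthetic experiment.

    ``edges`` maps ordered pairs (upstream, downstream) to propagation
    kernels.  Extrasynaptic-flagged edges exist functionally but are absent
    from the matched connectome; inhibitory edges carry kernels with negative
    integral.  The autoresponse template is the stimulated neuron's own
    dF/F0 transient (double-exponential rise/decay).
    """

    n_neurons: int
    edges: dict[tuple[int, int], Kernel]
    inhibitory_flags: dict[tuple[int, int], bool]
    extrasynaptic_flags: dict[tuple[int, int], bool]
    autoresponse_tau_rise: float = 1.5
    autoresponse_tau_decay: float = 8.0

    def __post_init__(self) -> None:
        for (j, i) in self.edges:
            if j == i:
                raise ValueError("self-edges are not allowed")
        for e, inh in self.inhibitory_flags.items():
            if inh and self.edges[e].integral() >= 0:
                raise ValueError(f"inhibitory edge {e} must have negative kernel integral")

    def autoresponse(self, t: np.ndarray, peak: float = 1.0) -> np.ndarray:
        """Double-exponential calcium transient, normalized to the given peak."""
        tr, td = self.autoresponse_tau_rise, self.autoresponse_tau_decay
        shape = np.where(t >= 0, np.exp(-np.maximum(t, 0) / td) - np.exp(-np.maximum(t, 0) / tr), 0.0)
        tpk = tr * td / (td - tr) * np.log(td / tr)
        norm = np.exp(-tpk / td) - np.exp(-tpk / tr)
        return peak * shape / norm

    def dc_gain_matrix(self) -> np.ndarray:
        g = np.zeros((self.n_neurons, self.n_neurons))
        for (j, i), k in self.edges.items():
            g[i, j] = k.integral()
        return g


def gen_ground_truth(
    n_neurons: int,
    edge_density: float,
    frac_inhibitory: float = 0.11,
    frac_extrasynaptic: float = 0.0,
    seed: int = 0,
    rate_band: tuple[float, float] = (0.05, 2.0),
    gain_band: tuple[float, float] = (0.1, 0.6),
) -> GroundTruthNetwork:
    """Draw a random functional network with kernel-labelled edges.

    Each ordered pair (no self-edges) carries an edge with probability
    ``edge_density``; edges are independently flagged inhibitory (default 11%,
    the observed fraction of inhibitory functional connections) and
    extrasynaptic.  Kernels are 1- or 2-chain with log-uniform rates.  The
    induced linear network must be stable (spectral radius of the DC-gain
    matrix < 1), otherwise the draw is rejected with a diagnostic.
    """
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    for f in (edge_density, frac_inhibitory, frac_extrasynaptic):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[int, int], Kernel] = {}
    inh: dict[tuple[int, int], bool] = {}
    ext: dict[tuple[int, int], bool] = {}
    for j in range(n_neurons):
        for i in range(n_neurons):
            if i == j or rng.random() >= edge_density:
                continue
            is_inh = bool(rng.random() < frac_inhibitory)
            is_ext = bool(rng.random() < frac_extrasynaptic)
            edges[(j, i)] = random_kernel(rng, rate_band=rate_band,
                                          gain_band=gain_band, inhibitory=is_inh)
            inh[(j, i)] = is_inh
            ext[(j, i)] = is_ext
    net = GroundTruthNetwork(n_neurons, edges, inh, ext)
    if edges:
        rho = float(np.max(np.abs(np.linalg.eigvals(net.dc_gain_matrix()))))
        if rho >= 1.0:
            raise ValueError(
                f"unstable network: spectral radius {rho:.3f} >= 1 at DC gain; "
                "lower edge_density or kernel amplitudes")
    return net


def _stim_times(cfg: SimConfig) -> np.ndarray:
    # one target per isi window, centred so early/late events keep usable windows
    return (np.arange(cfg.n_stimuli) + 0.5) * cfg.isi


def _spontaneous_dff(net: GroundTruthNetwork, cfg: SimConfig,
                     rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Tonic background activity: random calcium transients in every neuron.

    Present identically in stimulation and control recordings; this is what
    makes the empirical null realistically broad (pure imaging noise would
    understate the control distribution's spread).
    """
    dff = np.zeros((t.size, net.n_neurons))
    if cfg.spont_rate <= 0:
        return dff
    for i in range(net.n_neurons):
        n_ev = rng.poisson(cfg.spont_rate * cfg.duration)
        for t0 in np.sort(rng.uniform(0.0, cfg.duration, n_ev)):
            amp = rng.uniform(0.3, 1.7) * cfg.spont_amp
            dff[:, i] += net.autoresponse(t - t0, peak=amp)
    return dff


def _bleach_curve(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    a1, r1, a2, r2 = cfg.bleach
    if a1 == 0.0 and a2 == 0.0:
        return np.ones_like(t)
    return a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)


def simulate_recording(
    net: GroundTruthNetwork,
    cfg: SimConfig,
    recursive: bool = False,
) -> Recording:
    """Simulate one stimulation-response recording.

    Raw fluorescence is ``baseline * (1 + dFF) * bleach(t) + noise``.  Each
    stimulus adds the autoresponse template to the target and, per functional
    edge (j -> i), the kernel-convolved autoresponse to the downstream neuron,
    gated by an independent Bernoulli(response_probability) draw per trial.
    With ``recursive=True`` the stimulus is instead propagated through the
    full linear network (effective-connection semantics, all paths).
    """
    rng = np.random.default_rng(cfg.seed)
    n_t, n_n = cfg.n_samples, net.n_neurons
    t = np.arange(n_t) * cfg.dt
    dff = _spontaneous_dff(net, cfg, rng, t)

    times = _stim_times(cfg)
    targets = rng.integers(0, n_n, size=times.size)
    log = pd.DataFrame({
        "time_s": times,
        "target_index": targets,
        "duration_s": np.full(times.size, cfg.stim_duration),
        "on_target": np.ones(times.size, dtype=bool),
    })

    out_edges: dict[int, list[tuple[int, Kernel]]] = {}
    for (j, i), k in net.edges.items():
        out_edges.setdefault(j, []).append((i, k))

    for t0, j in zip(times, targets):
        auto = net.autoresponse(t - t0, peak=cfg.autoresponse_peak)
        dff[:, j] += auto
        if recursive:
            dff += _propagate_linear(net, auto, cfg.dt, j, rng, cfg.response_probability)
        else:
            for i, k in out_edges.get(int(j), []):
                if rng.random() < cfg.response_probability:
                    dff[:, i] += apply_kernel(k, auto, cfg.dt)

    F = cfg.baseline * (1.0 + dff) * _bleach_curve(cfg, t)[:, None]
    F = F + rng.normal(0.0, cfg.noise_sd, size=F.shape)
    mask = rng.random(F.shape) < cfg.missing_fraction
    return Recording(F=F, mask=mask, dt=cfg.dt, stim_log=log, strain=cfg.strain)


def _propagate_linear(net, auto, dt, j, rng, p_resp, max_hops=4):
    """Recursive propagation of a stimulus over all network paths."""
    n_t = auto.size
    dff = np.zeros((n_t, net.n_neurons))
    frontier = {j: auto}
    for _ in range(max_hops):
        nxt: dict[int, np.ndarray] = {}
        for src, sig in frontier.items():
            for (jj, ii), k in net.edges.items():
                if jj != src:
                    continue
                if rng.random() >= p_resp:
                    continue
                contrib = apply_kernel(k, sig, dt)
                dff[:, ii] += contrib
                nxt[ii] = nxt.get(ii, np.zeros(n_t)) + contrib
        if not nxt:
            break
        frontier = nxt
    return dff


def simulate_control(net: GroundTruthNetwork, cfg: SimConfig) -> Recording:
    """Identical generative model with an empty stimulation log (empirical null)."""
    rng = np.random.default_rng(cfg.seed)
    n_t = cfg.n_samples
    t = np.arange(n_t) * cfg.dt
    dff = _spontaneous_dff(net, cfg, rng, t)
    F = cfg.baseline * (1.0 + dff) * _bleach_curve(cfg, t)[:, None]
    F = F + rng.normal(0.0, cfg.noise_sd, size=F.shape)
    mask = rng.random(F.shape) < cfg.missing_fraction
    return Recording(F=F, mask=mask, dt=cfg.dt, stim_log=_empty_log(),
                     strain=cfg.strain)


def knockout_extrasynaptic(net: GroundTruthNetwork) -> GroundTruthNetwork:
    """The unc-31-like network: all extrasynaptic edges silenced.

    Emulates loss of dense-core-vesicle-mediated signalling; wired (synaptic)
    functional edges are untouched.
    """
    keep = {e for e in net.edges if not net.extrasynaptic_flags.get(e, False)}
    return GroundTruthNetwork(
        n_neurons=net.n_neurons,
        edges={e: net.edges[e] for e in keep},
        inhibitory_flags={e: net.inhibitory_flags[e] for e in keep},
        extrasynaptic_flags={e: False for e in keep},
        autoresponse_tau_rise=net.autoresponse_tau_rise,
        autoresponse_tau_decay=net.autoresponse_tau_decay,
    )


def gen_connectome(net: GroundTruthNetwork, extra_anatomy_edges: int = 0,
                   seed: int = 0, count_scale: float = 15.0) -> Connectome:
    """Matched wiring diagram: every non-extrasynaptic functional edge, plus
    anatomical-only (functionally silent) edges.

    Synapse counts are positive integers, noisily proportional to the edge's
    functional strength (|kernel integral|): anatomically stronger contacts
    tend to transmit more.  Inhibitory functional edges get negative polarity.
    Extrasynaptic edges are absent by construction.
    """
    rng = np.random.default_rng(seed)
    n = net.n_neurons
    chem = np.zeros((n, n))
    sign = np.ones((n, n))
    for (j, i), k in net.edges.items():
        if net.extrasynaptic_flags.get((j, i), False):
            continue
        gain = abs(k.integral())
        chem[i, j] = max(1, round(gain * count_scale * rng.uniform(0.7, 1.3)))
        sign[i, j] = -1.0 if net.inhibitory_flags.get((j, i), False) else 1.0
    free = [(j, i) for j in range(n) for i in range(n)
            if i != j and chem[i, j] == 0 and (j, i) not in net.edges]
    if extra_anatomy_edges > len(free):
        raise ValueError("not enough non-functional pairs for extra anatomy edges")
    idx = rng.choice(len(free), size=extra_anatomy_edges, replace=False) if extra_anatomy_edges else []
    for m in np.asarray(idx, dtype=int):
        j, i = free[m]
        # wired-but-silent contacts are typically weak
        chem[i, j] = int(rng.integers(1, 4))
    gap = np.zeros((n, n))
    return Connectome(chem, gap, sign)
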