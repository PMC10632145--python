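"""Anatomical connectome handling and connectome-constrained biophysics.

The connectome is a directed chemical-synapse count matrix plus a symmetric
gap-junction count matrix, with per-edge polarities.  This module computes
minimal anatomical path lengths (hop distances), simulates a leaky-integrator
network with graded chemical synapses and ohmic gap junctions to predict the
membrane-potential response of every neuron to in-silico current injection,
assigns polarities from a (possibly partial) sign table, fits edge weights and
signs to functional response amplitudes under the wiring-mask constraint, and
reports agreement through a through-origin regression R².

Units are SI throughout (volts, siemens, farads, amperes, seconds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, root

logger = logging.getLogger(__name__)

#: Predicted responses above this peak |dV| (volts) count as "large".
DV_LARGE = 0.1


@dataclass
class Connectome:
    """Chemical (directed, post x pre) and gap-junction (symmetric) count matrices.

    ``sign[i, j]`` is the polarity (+1 excitatory / -1 inhibitory) of the
    chemical edge from presynaptic ``j`` onto postsynaptic ``i``; it is
    meaningful wherever ``chem[i, j] > 0``.
    """

    chem: np.ndarray
    gap: np.ndarray
    sign: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chem = np.asarray(self.chem, dtype=float)
        self.gap = np.asarray(self.gap, dtype=float)
        n = self.chem.shape[0]
        if self.chem.shape != (n, n) or self.gap.shape != (n, n):
            raise ValueError("chem and gap must be square and same size")
        if np.any(self.chem < 0) or np.any(self.gap < 0):
            raise ValueError("synapse counts must be non-negative")
        if not np.allclose(self.gap, self.gap.T):
            raise ValueError("gap-junction matrix must be symmetric")
        if self.sign is None:
            self.sign = np.ones((n, n))
        else:
            self.sign = np.asarray(self.sign, dtype=float)
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.chem.shape[0]

    # --- CSV edge-list interface --------------------------------------
    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for j in range(self.n):
                if self.chem[i, j] > 0:
                    rows.append((self.labels[j], self.labels[i], "chem",
                                 self.chem[i, j], int(self.sign[i, j])))
                if j < i and self.gap[i, j] > 0:
                    rows.append((self.labels[j], self.labels[i], "gap",
                                 self.gap[i, j], 1))
        return pd.DataFrame(rows, columns=["pre", "post", "type", "count", "sign"])

    def to_csv(self, path) -> None:
        self.to_edge_list().to_csv(path, index=False)

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, labels: list[str] | None = None) -> "Connectome":
        if labels is None:
            labels = sorted(set(df["pre"]) | set(df["post"]))
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        chem = np.zeros((n, n))
        gap = np.zeros((n, n))
        sign = np.ones((n, n))
        for _, r in df.iterrows():
            j, i = idx[r["pre"]], idx[r["post"]]
            if r["type"] == "chem":
                chem[i, j] = r["count"]
                sign[i, j] = r["sign"]
            else:
                gap[i, j] = gap[j, i] = r["count"]
        return cls(chem, gap, sign, list(labels))

    @classmethod
    def from_csv(cls, path, labels: list[str] | None = None) -> "Connectome":
        return cls.from_edge_list(pd.read_csv(path), labels)


def average_connectomes(counts: list[np.ndarray]) -> np.ndarray:
    """Scaled average of several count matrices.

    Each dataset is first normalized by its total synapse count (so animals
    with denser reconstructions do not dominate), averaged, then rescaled to
    the mean total count.
    """
    counts = [np.asarray(c, float) for c in counts]
    totals = [c.sum() for c in counts]
    mean_total = float(np.mean(totals))
    normed = [c / t if t > 0 else c for c, t in zip(counts, totals)]
    return np.mean(normed, axis=0) * mean_total


# ----------------------------------------------------------------------
# hop distances
# ----------------------------------------------------------------------

@dataclass
class HopMatrix:
    """Minimal anatomical path lengths in hops; np.inf where unreachable."""

    l: np.ndarray


def hop_distances(c: Connectome) -> HopMatrix:
    """Iterative composition of the binarized connectome into strictly n-hop maps.

    A pair unconnected at < n hops is connected at n hops if joined through an
    intermediate; chemical edges are directed, gap junctions bidirectional.
    Equivalent to breadth-first-search distance on the binarized union graph.
    """
    n = c.n
    a = ((c.chem > 0) | (c.gap > 0)).astype(bool)
    np.fill_diagonal(a, False)
    l = np.full((n, n), np.inf)
    np.fill_diagonal(l, 0.0)
    reach = a.copy()
    l[a] = 1.0
    hop = 1
    while True:
        new = (reach @ a) & ~reach
        np.fill_diagonal(new, False)
        new &= np.isinf(l)
        if not new.any():
            break
        hop += 1
        l[new] = hop
        reach |= new
    return HopMatrix(l)


# ----------------------------------------------------------------------
# biophysical model
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BiophysParams:
    """Leaky-integrator parameters with graded synaptic activation.

    Defaults are in the range commonly used for *C. elegans* network models:
    10 pS leak, 1 pF capacitance, -35 mV leak reversal, 100 pS per gap-junction
    contact and per chemical synapse, activation rise 1/s and decay 5/s, and a
    logistic activation curve of slope 0.125 per mV whose midpoint is solved
    per neuron so that the network is exactly at rest before stimulation.
    """

    capacitance: float = 1e-12        # F
    g_leak: float = 1e-11             # S
    e_leak: float = -0.035            # V
    g_gap_unit: float = 1e-10         # S per gap contact
    g_syn_unit: float = 1e-10         # S per chemical synapse
    e_exc: float = 0.0                # V
    e_inh: float = -0.070             # V
    a_rise: float = 1.0               # 1/s
    a_decay: float = 5.0              # 1/s
    beta: float = 125.0               # 1/V (0.125 per mV)

    def __post_init__(self) -> None:
        for name in ("capacitance", "g_leak", "g_gap_unit", "g_syn_unit",
                     "a_rise", "a_decay", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _syn_matrices(c: Connectome, p: BiophysParams):
    g_gap = p.g_gap_unit * c.gap
    g_syn = p.g_syn_unit * c.chem
    e_rev = np.where(c.sign >= 0, p.e_exc, p.e_inh)
    return g_gap, g_syn, e_rev


def resting_state(c: Connectome, p: BiophysParams):
    """Resting potentials, activations, and per-neuron activation midpoints.

    At rest each activation sits at the value implied by a half-activated
    logistic (``phi = 1/2``), and the midpoint ``V_th`` is set to the resting
    potential so this is self-consistent; the membrane equation then becomes
    linear and is solved directly.
    """
    g_gap, g_syn, e_rev = _syn_matrices(c, p)
    s_eq = 0.5 * p.a_rise / (0.5 * p.a_rise + p.a_decay)
    n = c.n
    diag = p.g_leak + g_gap.sum(axis=1) + (g_syn * s_eq).sum(axis=1)
    a = np.diag(diag) - g_gap
    b = p.g_leak * p.e_leak + (g_syn * s_eq * e_rev).sum(axis=1)
    v_rest = np.linalg.solve(a, b)
    return v_rest, np.full(n, s_eq), v_rest.copy()  # v_th := v_rest


def biophys_simulate(
    c: Connectome,
    p: BiophysParams,
    stim: int,
    current: float,
    duration: float,
    t_total: float = 30.0,
    dt_out: float = 0.1,
):
    """Integrate the network response to a step current into one neuron.

    Returns ``(t, dV)`` with ``dV[t, i] = V_i(t) - V_rest,i``.  The model is

        C dV_i/dt = -g_l (V_i - E_l) - sum_j g_gap,ij (V_i - V_j)
                    - sum_j g_syn,ij s_j (V_i - E_rev,ij) + I_i
        ds_j/dt   = a_r phi(V_j) (1 - s_j) - a_d s_j

    with logistic ``phi``.  Starting from the computed rest state, zero input
    preserves equilibrium to solver precision.
    """
    g_gap, g_syn, e_rev = _syn_matrices(c, p)
    v_rest, s_eq, v_th = resting_state(c, p)
    n = c.n
    gap_row = g_gap.sum(axis=1)

    def phi(v):
        return 1.0 / (1.0 + np.exp(np.clip(-p.beta * (v - v_th), -500, 500)))

    def rhs(t, y, i_ext):
        v, s = y[:n], y[n:]
        i_mem = (-p.g_leak * (v - p.e_leak)
                 - gap_row * v + g_gap @ v
                 - (g_syn * (v[:, None] - e_rev)) @ s
                 + i_ext)
        ds = p.a_rise * phi(v) * (1.0 - s) - p.a_decay * s
        return np.concatenate([i_mem / p.capacitance, ds])

    i_on = np.zeros(n)
    i_on[stim] = current
    y0 = np.concatenate([v_rest, s_eq])
    # integrate the on- and off-segments separately: the input is discontinuous
    spans = [(0.0, min(duration, t_total), i_on)]
    if t_total > duration:
        spans.append((duration, t_total, np.zeros(n)))
    t_all, v_all = [], []
    y = y0
    for t0, t1, i_ext in spans:
        t_eval = np.linspace(t0, t1, max(int(round((t1 - t0) / dt_out)), 1) + 1)
        sol = solve_ivp(rhs, (t0, t1), y, args=(i_ext,), method="LSODA",
                        t_eval=t_eval, rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise RuntimeError(
                f"integration failed (max |V| = {np.max(np.abs(sol.y[:n])):.3g} V): "
                f"{sol.message}")
        t_all.append(sol.t)
        v_all.append(sol.y[:n].T)
        y = sol.y[:, -1]
    t = np.concatenate(t_all)
    v = np.vstack(v_all)
    return t, v - v_rest[None, :]


def steady_dv(c: Connectome, p: BiophysParams, stim: int, current: float) -> np.ndarray:
    """Fixed-point dV under sustained current injection (fast ODE-free route).

    At steady state the activation is a function of voltage,
    ``s(V) = a_r phi / (a_r phi + a_d)``, leaving n equations in V solved by
    a root finder started from rest.
    """
    g_gap, g_syn, e_rev = _syn_matrices(c, p)
    v_rest, _, v_th = resting_state(c, p)
    gap_row = g_gap.sum(axis=1)
    i_ext = np.zeros(c.n)
    i_ext[stim] = current

    def phi(v):
        return 1.0 / (1.0 + np.exp(np.clip(-p.beta * (v - v_th), -500, 500)))

    def f(v):
        s = p.a_rise * phi(v) / (p.a_rise * phi(v) + p.a_decay)
        return (-p.g_leak * (v - p.e_leak) - gap_row * v + g_gap @ v
                - (g_syn * (v[:, None] - e_rev)) @ s + i_ext) / p.g_leak

    sol = root(f, v_rest, method="hybr")
    if not sol.success:
        raise RuntimeError(f"steady-state solve failed: {sol.message}")
    return sol.x - v_rest


def dv_response_matrix(
    c: Connectome,
    p: BiophysParams,
    current: float = 1e-11,
    duration: float = 2.0,
    t_total: float = 30.0,
    method: str = "ode",
) -> np.ndarray:
    """Signed peak dV of every neuron under stimulation of every other neuron.

    Entry ``(i, j)`` is the peak-magnitude excursion of neuron i (keeping its
    sign) when neuron j is driven.  ``method='steady'`` uses the sustained-
    input fixed point instead of the transient peak; for step inputs that
    approach steady state monotonically the two coincide.
    """
    n = c.n
    out = np.zeros((n, n))
    for j in range(n):
        if method == "steady":
            dv_pk = steady_dv(c, p, j, current)
        else:
            _, dv = biophys_simulate(c, p, j, current, duration, t_total)
            idx = np.argmax(np.abs(dv), axis=0)
            dv_pk = dv[idx, np.arange(n)]
        out[:, j] = dv_pk
    np.fill_diagonal(out, 0.0)
    return out


# ----------------------------------------------------------------------
# polarities & weight fitting
# ----------------------------------------------------------------------

def _subtype(label: str) -> str:
    return label[:-1] if label and label[-1] in "LR" and len(label) > 1 else label


def assign_polarities(c: Connectome, sign_table: dict[tuple[str, str], int]) -> Connectome:
    """Set edge signs from a (possibly partial) polarity table.

    Table entries are aggregated across bilateral subtype members (trailing
    L/R stripped) by majority vote; ties and edges absent from the table are
    excitatory (+1).
    """
    agg: dict[tuple[str, str], list[int]] = {}
    for (pre, post), s in sign_table.items():
        agg.setdefault((_subtype(pre), _subtype(post)), []).append(int(np.sign(s)))
    sign = np.ones((c.n, c.n))
    for i, post in enumerate(c.labels):
        for j, pre in enumerate(c.labels):
            votes = agg.get((_subtype(pre), _subtype(post)))
            if votes and sum(votes) < 0:
                sign[i, j] = -1.0
    return replace_sign(c, sign)


def replace_sign(c: Connectome, sign: np.ndarray) -> Connectome:
    return Connectome(c.chem.copy(), c.gap.copy(), sign, list(c.labels))


@dataclass
class AgreementReport:
    """Through-origin regression of measured amplitudes on predicted dV."""

    slope: float
    r2: float
    dv: np.ndarray | None = None


def r2_agreement(measured: np.ndarray, predicted: np.ndarray) -> AgreementReport:
    """Fit ``measured = m * predicted`` through the origin; report m and R².

    R² is taken about the measured mean, so it can be negative when the
    anatomy-based prediction does worse than a constant.
    """
    meas = np.asarray(measured, float).ravel()
    pred = np.asarray(predicted, float).ravel()
    if meas.shape != pred.shape:
        raise ValueError("measured and predicted must be paired")
    if not np.any(pred):
        raise ValueError("all-zero prediction: slope undefined")
    m = float(np.dot(meas, pred) / np.dot(pred, pred))
    ss_res = float(np.sum((meas - m * pred) ** 2))
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return AgreementReport(slope=m, r2=r2)


def fit_weights(
    c: Connectome,
    measured: dict[tuple[int, int], float],
    p: BiophysParams | None = None,
    current: float = 1e-11,
    w_max: float = 50.0,
    n_starts: int = 2,
    seed: int = 0,
    max_nfev: int = 40,
) -> tuple[Connectome, AgreementReport]:
    """Fit signed chemical-edge weights to measured pair amplitudes.

    Only edges present in the wiring diagram carry free parameters (signed
    synapse-count-like magnitudes); absent edges stay exactly zero.  The loss
    is the residual of the through-origin scaling fit between measured
    amplitudes and the model's steady-state dV predictions.  Multistart,
    seeded; returns the best connectome and its agreement report.
    """
    p = BiophysParams() if p is None else p
    rng = np.random.default_rng(seed)
    edges = np.argwhere(c.chem > 0)  # (i=post, j=pre)
    pairs = sorted(measured)
    meas = np.array([measured[pr] for pr in pairs])

    def build(w: np.ndarray) -> Connectome:
        chem = np.zeros_like(c.chem)
        sign = np.ones_like(c.sign)
        for (i, j), wij in zip(edges, w):
            chem[i, j] = abs(wij)
            sign[i, j] = 1.0 if wij >= 0 else -1.0
        return Connectome(chem, c.gap, sign, list(c.labels))

    def predict(w: np.ndarray) -> np.ndarray:
        # measured pairs are keyed (pre, post); dv is post x pre
        dv = dv_response_matrix(build(w), p, current=current, method="steady")
        return np.array([dv[post, pre] for (pre, post) in pairs])

    def resid(w: np.ndarray) -> np.ndarray:
        pred = predict(w)
        denom = float(np.dot(pred, pred))
        if denom == 0:
            return meas
        m = float(np.dot(meas, pred)) / denom
        return meas - m * pred

    best = None
    x_init = (c.chem[c.chem > 0] * c.sign[c.chem > 0]).astype(float)
    for s in range(n_starts):
        x0 = x_init if s == 0 else x_init * rng.uniform(0.3, 2.0, x_init.size) * rng.choice([-1, 1], x_init.size)
        try:
            sol = least_squares(resid, x0, bounds=(-w_max, w_max),
                                max_nfev=max_nfev, diff_step=0.05)
        except Exception as exc:  # pragma: no cover
            logger.warning("weight fit start %d failed: %s", s, exc)
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:  # pragma: no cover
        logger.warning("weight fit failed on all starts; returning input weights")
        best = (np.inf, x_init)
    fitted = build(best[1])
    pred = predict(best[1])
    rep = r2_agreement(meas, pred)
    rep.dv = None
    return fitted, rep
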