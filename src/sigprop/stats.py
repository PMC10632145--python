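"""Statistical framework for calling functional connections.

Each ordered neuron pair's post-stimulus response summaries (per-observation
mean dF/F0 and max |second derivative|) are compared against empirical null
distributions built from control recordings that lack stimulation.  Two-sided
Kolmogorov-Smirnov p-values for the two summaries are fused with Fisher's
method, and the false discovery rate over all pairs is controlled with
Storey-Tibshirani q-values: a pair is "functionally connected" at q < 0.05.
A pair is "functionally non-connected" when a two-one-sided-test (TOST)
equivalence procedure bounds its mean summaries within epsilon = 1.2 sigma of
the null (sigma being the null summary's SD), again Fisher-fused across the
two summaries and FDR-adjusted (q_eq < 0.05).  Pairs passing neither test are
undetermined.  A WT vs unc-31 contrast screens for connections that exist in
the wild type but are equivalent to null in the mutant -- candidate purely
extrasynaptic (dense-core-vesicle-dependent) connections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.weightstats import ttost_ind

from .screen import Observation, response_amplitude
from .synth import Recording, SimConfig
from .traces import RawTraceSet, preprocess, response_window, second_derivative

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.05
EPS_FACTOR = 1.2


@dataclass
class NullDistributions:
    """Pooled pseudo-stimulation summaries from control recordings."""

    amp_samples: np.ndarray
    deriv_samples: np.ndarray

    def __post_init__(self) -> None:
        self.amp_samples = np.asarray(self.amp_samples, float)
        self.deriv_samples = np.asarray(self.deriv_samples, float)
        if self.amp_samples.size < 100:
            logger.warning("only %d null amplitude samples; >= 100 recommended",
                           self.amp_samples.size)

    @property
    def sigma_amp(self) -> float:
        return float(self.amp_samples.std(ddof=1))

    @property
    def sigma_deriv(self) -> float:
        return float(self.deriv_samples.std(ddof=1))


@dataclass
class PairObservationSet:
    """All response summaries for one ordered (stim, down) neuron pair."""

    pair: tuple[int, int]
    amps: np.ndarray
    derivs: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.amps.size


@dataclass
class PairStats:
    pair: tuple[int, int]
    n_obs: int
    amp_mean: float
    p_amp: float = 1.0
    p_deriv: float = 1.0
    p: float = 1.0
    q: float = 1.0
    p_eq: float = 1.0
    q_eq: float = 1.0
    label: str = "undetermined"


def observation_summaries(obs: Observation) -> tuple[float, float]:
    """(mean post-window dF/F0, max |second derivative| in the post window)."""
    w = obs.downstream_window
    amp = response_amplitude(w)
    d2 = second_derivative(w)[w.post_mask]
    return amp, float(np.max(np.abs(d2)))


def collect_pairs(observations: list[Observation]) -> dict[tuple[int, int], PairObservationSet]:
    """Group included observations into per-pair summary sets."""
    acc: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for o in observations:
        if not o.included:
            continue
        acc.setdefault((o.stim.target, o.downstream), []).append(observation_summaries(o))
    return {
        pr: PairObservationSet(pr, np.array([a for a, _ in v]), np.array([d for _, d in v]))
        for pr, v in acc.items()
    }


def build_null(controls: list[Recording], schedule: SimConfig | None = None) -> NullDistributions:
    """Pool pseudo-stimulation summaries from control (no-stimulation) recordings.

    Pseudo-stimulation times mimic the real schedule (one per isi window); for
    every pseudo-event and neuron the same per-observation summaries used for
    real pairs are computed and pooled across recordings.
    """
    if not controls:
        raise ValueError("no control recordings supplied; run simulate_control first")
    isi = schedule.isi if schedule is not None else 30.0
    amps, ders = [], []
    for rec in controls:
        if len(rec.stim_log):
            raise ValueError("control recordings must have an empty stimulation log")
        pre = preprocess(RawTraceSet(rec.F, rec.mask, rec.dt, list(rec.labels)))
        duration = rec.F.shape[0] * rec.dt
        times = (np.arange(int(duration // isi)) + 0.5) * isi
        for t0 in times:
            for i in range(rec.F.shape[1]):
                w = response_window(pre, t0, i)
                amps.append(response_amplitude(w))
                d2 = second_derivative(w)[w.post_mask]
                ders.append(float(np.max(np.abs(d2))))
    return NullDistributions(np.array(amps), np.array(ders))


def ks_pair_pvalues(obs: PairObservationSet, null: NullDistributions) -> tuple[float, float]:
    """Two-sided two-sample KS p-values for the amplitude and derivative summaries."""
    if null.amp_samples.size == 0:
        raise ValueError("empty null distribution")
    if obs.n_obs < 1:
        raise ValueError("need at least one observation")
    p_amp = sps.ks_2samp(obs.amps, null.amp_samples, alternative="two-sided").pvalue
    p_der = sps.ks_2samp(obs.derivs, null.deriv_samples, alternative="two-sided").pvalue
    return float(p_amp), float(p_der)


_TINY = np.finfo(float).tiny


def fisher_combine(p_a: float, p_b: float) -> float:
    """Fisher's method: chi-square(4 df) upper tail of -2(ln p_a + ln p_b).

    Zero inputs are clamped to the smallest positive float (logged).
    """
    ps = []
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
        if p == 0.0:
            logger.warning("p-value of exactly 0 clamped to %g", _TINY)
            p = _TINY
        ps.append(p)
    stat = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(sps.chi2.sf(stat, df=4))


def storey_qvalues(p_list: np.ndarray) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated on the lambda grid 0, 0.05, ..., 0.90 via a cubic
    polynomial smoother evaluated at the largest lambda, clipped to (0, 1];
    q_i = min over p_j >= p_i of pi0 * M * p_j / rank(p_j), monotone in p.
    """
    p = np.asarray(p_list, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_list must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < 10:
        logger.warning("only %d p-values; Storey pi0 estimate is unreliable", m)
    lam = np.arange(0.0, 0.95, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m >= 10:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam[-1]))
    else:
        pi0 = float(pi0_lam[-1])
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotonicity in p
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def tost_pair_pvalue(obs: PairObservationSet, null: NullDistributions,
                     eps_factor: float = EPS_FACTOR) -> float:
    """Equivalence p-value: Welch TOST within eps = eps_factor * sigma, Fisher-fused.

    For each summary (amplitude; second derivative) a two-sample Welch TOST
    tests |mean(pair) - mean(null)| < eps with sigma the null summary's SD;
    the per-summary p_eq is the max of the two one-sided p-values, and the two
    summaries are fused with Fisher's method.  Fewer than two observations
    cannot support an equivalence claim (p_eq = 1, logged).
    """
    if obs.n_obs < 2:
        logger.info("pair %s has n_obs=%d < 2; equivalence undecidable", obs.pair, obs.n_obs)
        return 1.0
    p_parts = []
    for x, nullx, sigma in ((obs.amps, null.amp_samples, null.sigma_amp),
                            (obs.derivs, null.deriv_samples, null.sigma_deriv)):
        eps = eps_factor * sigma
        p_eq, t1, t2 = ttost_ind(x, nullx, -eps, eps, usevar="unequal")
        p_parts.append(float(p_eq))  # max of the two one-sided p-values
    return fisher_combine(p_parts[0], p_parts[1])


def classify_pairs(stats_list: list[PairStats],
                   q_threshold: float = Q_THRESHOLD) -> list[PairStats]:
    """Assign connected / non_connected / undetermined labels.

    connected iff q < threshold; non_connected iff q_eq < threshold and the
    pair is not connected; undetermined otherwise (no pair carries both labels).
    """
    for st in stats_list:
        if st.q < q_threshold:
            st.label = "connected"
        elif st.q_eq < q_threshold:
            st.label = "non_connected"
        else:
            st.label = "undetermined"
    return stats_list


def compute_pair_stats(pairs: dict[tuple[int, int], PairObservationSet],
                       null: NullDistributions,
                       eps_factor: float = EPS_FACTOR) -> list[PairStats]:
    """Full per-pair table: KS -> Fisher -> Storey q, TOST -> Storey q_eq, labels."""
    stats_list: list[PairStats] = []
    for pr, po in sorted(pairs.items()):
        p_amp, p_der = ks_pair_pvalues(po, null)
        st = PairStats(pair=pr, n_obs=po.n_obs, amp_mean=float(po.amps.mean()),
                       p_amp=p_amp, p_deriv=p_der,
                       p=fisher_combine(p_amp, p_der),
                       p_eq=tost_pair_pvalue(po, null, eps_factor))
        stats_list.append(st)
    if stats_list:
        q = storey_qvalues(np.array([s.p for s in stats_list]))
        q_eq = storey_qvalues(np.array([s.p_eq for s in stats_list]))
        for s, qv, qe in zip(stats_list, q, q_eq):
            s.q = float(qv)
            s.q_eq = float(qe)
    return classify_pairs(stats_list)


def extrasynaptic_screen(wt: list[PairStats], mut: list[PairStats],
                         q_threshold: float = Q_THRESHOLD) -> list[tuple[int, int]]:
    """Pairs connected in WT and non-connected in the mutant.

    Returns pairs with q_WT < threshold AND q_eq_mut < threshold AND
    q_mut > threshold (the last condition excludes small-but-significant
    mutant responses).  Pairs absent from either atlas are skipped (counted).
    """
    wt_by = {s.pair: s for s in wt}
    mut_by = {s.pair: s for s in mut}
    missing = 0
    hits = []
    for pr, sw in sorted(wt_by.items()):
        sm = mut_by.get(pr)
        if sm is None:
            missing += 1
            continue
        if sw.q < q_threshold and sm.q_eq < q_threshold and sm.q > q_threshold:
            hits.append(pr)
    missing += len(set(mut_by) - set(wt_by))
    if missing:
        logger.info("extrasynaptic screen: %d pairs absent from one atlas", missing)
    return hits
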