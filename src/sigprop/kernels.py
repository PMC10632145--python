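"""Causal signal-propagation kernels as sums of convolved decaying exponentials.

A kernel ``k_ij(t)`` maps the calcium activity of a stimulated (upstream)
neuron ``j`` onto the activity of a downstream neuron ``i`` through causal
convolution, ``dF_i = k_ij * dF_j``.  Each kernel is parametrized as

    k(t) = sum_m  c_m * (theta(t) e^{-g_{m,0} t}) * (theta(t) e^{-g_{m,1} t}) * ...

where ``theta`` is the Heaviside step and ``*`` denotes convolution.  The
convolutions are carried out symbolically: a repeated convolution of decaying
exponentials is always a finite sum of terms of the form
``a * theta(t) * t^n * e^{-g t}``, and closed-form rules map any such term
convolved with one more exponential back onto the same family.  Two chains in
the sum (with opposite-sign coefficients) suffice to represent saturating
signal transfer, so the fit is capped at two chains.

The module provides the symbolic algebra, pointwise/discrete evaluation,
least-squares kernel fitting with small-sample model selection, rise-time
measurement with desaturation, and round-robin stereotypy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Bounds on decay rates (1/s) used by the fitter.  The lower bound reflects
#: the 30-s response window (slower components are unidentifiable), the upper
#: bound the 0.5-s sampling of the recordings.
RATE_MIN = 1.0 / 60.0
RATE_MAX = 10.0


@dataclass(frozen=True)
class CanonicalTerm:
    """One term ``a * theta(t) * t^n * e^{-gamma t}`` of the canonical expansion."""

    a: float
    n: int
    gamma: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("power n must be non-negative")
        if self.gamma <= 0:
            raise ValueError("rate gamma must be positive")

    def integral(self) -> float:
        """Integral over [0, inf): a * n! / gamma^(n+1)."""
        return self.a * np.exp(gammaln(self.n + 1) - (self.n + 1) * np.log(self.gamma))


@dataclass(frozen=True)
class ExpChainTerm:
    """One summand of the kernel: ``c * (theta e^{-g0 t}) * (theta e^{-g1 t}) * ...``."""

    c: float
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        rates = tuple(float(g) for g in self.rates)
        object.__setattr__(self, "rates", rates)
        if len(rates) < 1:
            raise ValueError("chain needs at least one rate")
        if any(g <= 0 for g in rates):
            raise ValueError("all rates must be strictly positive")

    def integral(self) -> float:
        """Each un-normalized exponential factor integrates to 1/gamma."""
        return self.c * float(np.prod([1.0 / g for g in self.rates]))


def convolve_exp(term: CanonicalTerm, gamma_n: float) -> list[CanonicalTerm]:
    """Convolve a canonical term with a *normalized* exponential ``gamma_n theta(t) e^{-gamma_n t}``.

    Implements the four closed-form rules.  Equal-rate detection is by exact
    floating-point comparison: the fitter treats equal-rate chains as a
    distinct model class, so near-duplicate rates never arise from that path
    and the numerically unstable ``gamma_n - gamma_i -> 0`` limit is avoided.
    """
    if gamma_n <= 0:
        raise ValueError("gamma_n must be positive")
    ci, n, gi = term.a, term.n, term.gamma
    if n == 0:
        if gi != gamma_n:
            # simple exponential, distinct rates -> two exponentials
            c_mu = ci * gamma_n / (gamma_n - gi)
            return [CanonicalTerm(c_mu, 0, gi), CanonicalTerm(-c_mu, 0, gamma_n)]
        # equal rates -> t e^{-gt}
        return [CanonicalTerm(ci * gi, 1, gi)]
    if gi == gamma_n:
        # power term, equal rates -> power n+1
        return [CanonicalTerm(ci * gi / (n + 1), n + 1, gi)]
    # power term, distinct rates -> recursion
    c_mu = ci * gamma_n / (gamma_n - gi)
    out = [CanonicalTerm(c_mu, n, gi)]
    tail = CanonicalTerm(-n * c_mu / gamma_n, n - 1, gi)
    out.extend(convolve_exp(tail, gamma_n))
    return out


def _merge_terms(terms: list[CanonicalTerm]) -> list[CanonicalTerm]:
    acc: dict[tuple[int, float], float] = {}
    for t in terms:
        key = (t.n, t.gamma)
        acc[key] = acc.get(key, 0.0) + t.a
    return [CanonicalTerm(a, n, g) for (n, g), a in sorted(acc.items()) if a != 0.0]


@dataclass
class Kernel:
    """A causal kernel: a sum of at most a few exponential-convolution chains.

    The canonical expansion (terms ``a t^n e^{-gt}``) is derived lazily and
    numerically equals the chain form; ``k(t) = 0`` for ``t < 0``.
    """

    chains: list[ExpChainTerm] = field(default_factory=list)
    _canonical: list[CanonicalTerm] | None = field(default=None, repr=False, compare=False)

    @property
    def canonical(self) -> list[CanonicalTerm]:
        if self._canonical is None:
            self._canonical = to_canonical(self)
        return self._canonical

    def is_zero(self) -> bool:
        return len(self.chains) == 0

    def integral(self) -> float:
        return float(sum(ch.integral() for ch in self.chains))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return eval_kernel(self, t)

    # --- plain-text serialization -------------------------------------
    def to_dict(self) -> dict:
        return {"chains": [{"c": ch.c, "rates": list(ch.rates)} for ch in self.chains]}

    @classmethod
    def from_dict(cls, d: dict) -> "Kernel":
        return cls([ExpChainTerm(ch["c"], tuple(ch["rates"])) for ch in d["chains"]])


def to_canonical(k: Kernel) -> list[CanonicalTerm]:
    """Expand each chain left-to-right via the convolution rules and merge.

    Chain factors are the un-normalized ``theta(t) e^{-g t}``; since the rules
    convolve with the *normalized* exponential ``g theta(t) e^{-g t}``, each
    fold divides by the convolving rate.
    """
    out: list[CanonicalTerm] = []
    for ch in k.chains:
        terms = [CanonicalTerm(ch.c, 0, ch.rates[0])]
        for g in ch.rates[1:]:
            folded: list[CanonicalTerm] = []
            for t in terms:
                folded.extend(CanonicalTerm(u.a / g, u.n, u.gamma) for u in convolve_exp(t, g))
            terms = _merge_terms(folded)
        out.extend(terms)
    return _merge_terms(out)


def eval_kernel(k: Kernel, t_grid: np.ndarray) -> np.ndarray:
    """Pointwise evaluation of the canonical form; exactly 0 for t < 0."""
    t = np.asarray(t_grid, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    for term in k.canonical:
        # exp in log-space guards against overflow of t^n for large t
        with np.errstate(divide="ignore"):
            logmag = term.n * np.log(np.where(tp > 0, tp, 1.0)) - term.gamma * tp
        val = term.a * np.exp(logmag)
        if term.n > 0:
            val = np.where(tp > 0, val, 0.0)
        out[pos] += val
    return out


def apply_kernel(k: Kernel, upstream: np.ndarray, dt: float) -> np.ndarray:
    """Discrete causal convolution ``(k * upstream) * dt`` on the trace grid."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    u = np.asarray(upstream, dtype=float)
    if k.is_zero():
        return np.zeros_like(u)
    t = np.arange(u.size) * dt
    kv = eval_kernel(k, t)
    return np.convolve(u, kv)[: u.size] * dt


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

# model classes: tuples of chain lengths; two chains allow saturating kernels
_MODEL_CLASSES: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3,), (1, 1), (1, 2), (2, 2),
)


def _pack(chains: list[ExpChainTerm]) -> np.ndarray:
    x = []
    for ch in chains:
        x.append(ch.c)
        x.extend(np.log(ch.rates))
    return np.array(x)


def _unpack(x: np.ndarray, lengths: tuple[int, ...]) -> list[ExpChainTerm]:
    chains = []
    i = 0
    for L in lengths:
        c = x[i]
        rates = tuple(np.exp(x[i + 1 : i + 1 + L]))
        chains.append(ExpChainTerm(c, rates))
        i += 1 + L
    return chains


def _aicc(rss: float, n_pts: int, n_par: int) -> float:
    n_pts = max(n_pts, n_par + 2)
    aic = n_pts * np.log(max(rss, 1e-300) / n_pts) + 2 * n_par
    return aic + 2 * n_par * (n_par + 1) / (n_pts - n_par - 1)


def fit_kernel(
    upstream: np.ndarray,
    downstream: np.ndarray,
    dt: float,
    max_chains: int = 2,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
    models: tuple[tuple[int, ...], ...] | None = None,
) -> Kernel:
    """Least-squares fit of ``downstream ~ k * upstream`` over the window.

    Model selection over chain count (1..max_chains) and chain length (1-3)
    uses the small-sample corrected information criterion; each model class is
    started from several log-spaced rate initializations.  Returns the zero
    kernel if the downstream series is identically zero or no start converges.
    """
    u = np.asarray(upstream, float)
    d = np.asarray(downstream, float)
    if u.shape != d.shape:
        raise ValueError("upstream and downstream must share a grid")
    if not np.any(d):
        return Kernel()
    rng = np.random.default_rng(0) if rng is None else rng

    scale = np.max(np.abs(d)) / max(np.max(np.abs(u)), 1e-12)
    log_lo, log_hi = np.log(RATE_MIN), np.log(RATE_MAX)

    def resid(x: np.ndarray, lengths: tuple[int, ...]) -> np.ndarray:
        return apply_kernel(Kernel(_unpack(x, lengths)), u, dt) - d

    best: tuple[float, Kernel] | None = None
    for lengths in (models if models is not None else _MODEL_CLASSES):
        if len(lengths) > max_chains:
            continue
        n_par = sum(1 + L for L in lengths)
        lb, ub = [], []
        for L in lengths:
            lb.extend([-np.inf] + [log_lo] * L)
            ub.extend([np.inf] + [log_hi] * L)
        for s in range(n_starts):
            x0 = []
            for ci, L in enumerate(lengths):
                c0 = scale * (1.0 if ci == 0 else -0.5)
                g0 = np.exp(rng.uniform(np.log(0.05), np.log(2.0), size=L))
                x0.extend([c0, *np.log(g0)])
            try:
                sol = least_squares(
                    resid, np.array(x0), args=(lengths,),
                    bounds=(lb, ub), method="trf", max_nfev=200,
                )
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            rss = float(np.sum(sol.fun**2))
            score = _aicc(rss, d.size, n_par)
            kern = Kernel(_unpack(sol.x, lengths))
            if best is None or score < best[0]:
                best = (score, kern)
    if best is None:  # pragma: no cover
        logger.warning("kernel fit failed on all starts; returning zero kernel")
        return Kernel()
    return best[1]


# ----------------------------------------------------------------------
# rise time & stereotypy
# ----------------------------------------------------------------------

def desaturate(k: Kernel) -> Kernel:
    """Drop sum terms representing saturation (sign opposite the dominant chain).

    The dominant chain is the one with the largest ``|c * integral factor|``;
    a saturating kernel carries a second, opposite-sign chain that delays the
    apparent peak without reflecting the connection's intrinsic speed.
    """
    if k.is_zero():
        raise ValueError("cannot desaturate the zero kernel")
    weights = [abs(ch.integral()) for ch in k.chains]
    dom_sign = np.sign(k.chains[int(np.argmax(weights))].c)
    kept = [ch for ch in k.chains if np.sign(ch.c) == dom_sign]
    return Kernel(kept)


def rise_time(k: Kernel, t_max: float = 120.0, dt: float = 1e-3) -> float:
    """Time from the earliest 1/e-of-peak crossing to the peak of |k|, after desaturation.

    Returns 0.0 when the (desaturated) kernel peaks at t = 0, as for a single
    decaying exponential.
    """
    if k.is_zero():
        raise ValueError("rise time undefined for the zero kernel")
    kd = desaturate(k)
    t = np.arange(0.0, t_max, dt)
    v = np.abs(eval_kernel(kd, t))
    ipk = int(np.argmax(v))
    if ipk == 0:
        return 0.0
    peak = v[ipk]
    above = np.nonzero(v[: ipk + 1] >= peak / np.e)[0]
    return float(t[ipk] - t[above[0]])


def stereotypy(kernels: list[Kernel], stimuli: list[np.ndarray], dt: float) -> float:
    """Mean Pearson correlation across round-robin kernel pairings and stimuli.

    Each kernel is convolved with each common stimulus; outputs of every
    unordered kernel pair are compared; the mean over pairs and stimuli
    measures trial-to-trial consistency of a connection.
    """
    if len(kernels) < 2:
        raise ValueError("at least two kernels are required")
    if len(stimuli) < 1:
        raise ValueError("at least one stimulus is required")
    cors = []
    for stim in stimuli:
        outs = [apply_kernel(k, stim, dt) for k in kernels]
        for a, b in itertools.combinations(outs, 2):
            sa, sb = np.std(a), np.std(b)
            if sa == 0 or sb == 0:
                continue
            cors.append(float(np.corrcoef(a, b)[0, 1]))
    if not cors:
        raise ValueError("all kernel outputs constant; stereotypy undefined")
    return float(np.mean(cors))


def random_kernel(rng: np.random.Generator, max_chains: int = 2,
                  rate_band: tuple[float, float] = (0.05, 2.0),
                  gain_band: tuple[float, float] = (0.1, 0.6),
                  inhibitory: bool = False) -> Kernel:
    """Draw a random 1- or 2-chain kernel with log-uniform rates.

    The kernel is normalized so its integral (DC gain) lies in ``gain_band``
    in magnitude, keeping randomly wired networks stable; an inhibitory
    kernel has a negative integral.
    """
    n_chains = int(rng.integers(1, max_chains + 1))
    sgn = -1.0 if inhibitory else 1.0
    chains = []
    for m in range(n_chains):
        L = int(rng.integers(1, 3))
        rates = tuple(np.exp(rng.uniform(np.log(rate_band[0]), np.log(rate_band[1]), size=L)))
        if m == 0:
            c = sgn
        else:
            # second, opposite-sign chain: saturation; subdominant in integral
            lead = chains[0]
            c = -sgn * rng.uniform(0.1, 0.5) * abs(lead.integral()) * float(np.prod(rates))
        chains.append(ExpChainTerm(c, rates))
    gain = rng.uniform(*gain_band)
    total = abs(sum(ch.integral() for ch in chains))
    scale = gain / total
    return Kernel([ExpChainTerm(ch.c * scale, ch.rates) for ch in chains])
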