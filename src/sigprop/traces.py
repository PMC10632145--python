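"""Calcium-trace preprocessing and windowed dF/F0 extraction.

The five-step chain applied to raw fluorescence before any statistics:

1. interpolate missing samples (linear, nearest-value at the edges);
2. divide out photobleaching, fitted as a robust double exponential;
3. remove outliers beyond k standard deviations (default 5) per trace;
4. causal Savitzky-Golay smoothing (window 6.5 s = 13 samples at 2 vol/s,
   order 1, evaluated at the trailing edge so the filter is fully "in the
   past") -- used for display and statistics, never for kernel fits;
5. dF/F0 response windows: F0 is the mean fluorescence over the 30 s before
   a stimulus, dF = F - F0, windows span [-30, +30) s around the stimulus.

A causal Savitzky-Golay differentiator with the same 13-sample window supplies
the temporal second derivative used by the response classifier and the
connectivity statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_coeffs

logger = logging.getLogger(__name__)

SG_WINDOW = 13        # samples (6.5 s at dt = 0.5 s)
PRE_WINDOW_S = 30.0   # baseline interval before the stimulus
POST_WINDOW_S = 30.0  # response interval after the stimulus


@dataclass
class RawTraceSet:
    """Fluorescence matrix [time x neuron] with a missing-sample mask."""

    F: np.ndarray
    mask: np.ndarray
    dt: float
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.F.shape != self.mask.shape:
            raise ValueError("F and mask must have the same shape")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.F[~self.mask])):
            raise ValueError("F must be finite where not masked")
        if self.labels is None:
            self.labels = [f"n{i}" for i in range(self.F.shape[1])]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.F.shape[0]) * self.dt


@dataclass
class ResponseWindow:
    """dF/F0 on [-30, +30) s around a stimulus (half-open, stimulus at t=0)."""

    values: np.ndarray
    F0: float
    dt: float
    t: np.ndarray
    pre_mask: np.ndarray
    post_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.F0 <= 0:
            raise ValueError("baseline F0 must be positive")

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.post_mask]

    @property
    def pre_values(self) -> np.ndarray:
        return self.values[self.pre_mask]


# ----------------------------------------------------------------------
# step 1: interpolation
# ----------------------------------------------------------------------

def interpolate_missing(tr: RawTraceSet) -> RawTraceSet:
    """Fill missing samples per trace by linear interpolation in time.

    Interior gaps are bridged between the neighbouring present samples; gaps
    at the recording edges are held at the nearest present value.  Present
    samples are untouched and the output mask is all-false.
    """
    F = tr.F.copy()
    t = tr.time
    for i in range(F.shape[1]):
        miss = tr.mask[:, i]
        n_present = int((~miss).sum())
        if n_present < 2:
            raise ValueError(
                f"trace {tr.labels[i]!r} has {n_present} present samples; "
                "need at least 2 to interpolate")
        if miss.any():
            F[miss, i] = np.interp(t[miss], t[~miss], F[~miss, i])
    return replace(tr, F=F, mask=np.zeros_like(tr.mask))


# ----------------------------------------------------------------------
# step 2: photobleach correction
# ----------------------------------------------------------------------

def _double_exp(t, a1, r1, a2, r2):
    return a1 * np.exp(-r1 * t) + a2 * np.exp(-r2 * t)


def _fit_bleach(t: np.ndarray, y: np.ndarray, double: bool = True):
    """Robust (iteratively reweighted) non-negative double-exponential fit.

    Samples more than one weighted-residual SD *above* the running fit are
    down-weighted, so positive calcium transients do not drag the baseline.
    """
    y0, y1 = float(np.median(y[: max(len(y) // 10, 2)])), float(np.median(y[-max(len(y) // 10, 2):]))
    span = max(t[-1], 1.0)
    if double:
        x0 = np.array([max(y0 - y1, 1e-3), 2.0 / span, max(y1, 1e-3), 1e-9])
        lb = [0.0, 0.0, 0.0, 0.0]
        ub = [np.inf, np.inf, np.inf, np.inf]
        model = lambda x, tt: _double_exp(tt, *x)
    else:
        x0 = np.array([max(y0, 1e-3), 1.0 / span])
        lb = [0.0, 0.0]
        ub = [np.inf, np.inf]
        model = lambda x, tt: x[0] * np.exp(-x[1] * tt)
    w = np.ones_like(y)
    sol = None
    for _ in range(4):
        sol = least_squares(lambda x: w * (model(x, t) - y), x0, bounds=(lb, ub),
                            max_nfev=400)
        res = y - model(sol.x, t)
        sd = np.std(res[w > 0]) or 1.0
        w = np.where(res > sd, 0.1, 1.0)
        x0 = sol.x
    return sol, model


def correct_photobleach(tr: RawTraceSet) -> RawTraceSet:
    """Divide each trace by its fitted double-exponential baseline.

    The correction is renormalized so the baseline's initial value is
    preserved: ``F_out = F / b(t) * b(0)``.  A non-convergent double
    exponential falls back to a single exponential (logged).
    """
    if tr.mask.any():
        raise ValueError("interpolate_missing must run before bleach correction")
    F = tr.F.copy()
    t = tr.time
    for i in range(F.shape[1]):
        y = tr.F[:, i]
        try:
            sol, model = _fit_bleach(t, y, double=True)
            ok = sol.success
        except Exception:
            ok = False
        if not ok:
            logger.warning("double-exp bleach fit failed for %s; single-exp fallback",
                           tr.labels[i])
            sol, model = _fit_bleach(t, y, double=False)
        b = model(sol.x, t)
        b0 = b[0]
        if b0 <= 0 or np.any(b <= 0):
            logger.warning("degenerate bleach baseline for %s; trace left unchanged",
                           tr.labels[i])
            continue
        F[:, i] = y / b * b0
    return replace(tr, F=F)


# ----------------------------------------------------------------------
# step 3: outlier removal
# ----------------------------------------------------------------------

def remove_outliers(tr: RawTraceSet, k: float = 5.0) -> RawTraceSet:
    """Mark samples beyond k per-trace standard deviations missing and re-interpolate.

    One re-estimation pass: statistics are recomputed once after the first
    removal.  Constant traces (SD = 0) pass through unchanged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    out = tr
    for _ in range(2):  # initial pass + one re-estimation
        F = out.F
        mu = F.mean(axis=0)
        sd = F.std(axis=0)
        bad = np.abs(F - mu) > k * np.where(sd > 0, sd, np.inf)
        if not bad.any():
            break
        out = interpolate_missing(replace(out, mask=bad))
    return out


# ----------------------------------------------------------------------
# step 4: causal smoothing
# ----------------------------------------------------------------------

def _causal_sg(y: np.ndarray, window: int, order: int, deriv: int = 0,
               delta: float = 1.0) -> np.ndarray:
    """Savitzky-Golay filter evaluated at the trailing window position.

    The first ``window - 1`` samples use shrunken causal windows of the same
    form (smallest window that still supports the polynomial order).
    """
    n = y.size
    if n < window:
        raise ValueError(f"trace length {n} shorter than filter window {window}")
    out = np.empty(n)
    # steady state: dot the reversed coefficient vector with the past window
    c = savgol_coeffs(window, order, deriv=deriv, delta=delta, pos=window - 1, use="dot")
    for t in range(window - 1, n):
        out[t] = c @ y[t - window + 1 : t + 1]
    for t in range(window - 1):
        w = t + 1
        o = min(order, w - 1)
        if deriv > o:
            out[t] = 0.0
            continue
        cw = savgol_coeffs(w, o, deriv=deriv, delta=delta, pos=w - 1, use="dot") if w > 1 \
            else np.array([1.0 if deriv == 0 else 0.0])
        out[t] = cw @ y[: t + 1]
    return out


def smooth_causal(tr: RawTraceSet, window: int = SG_WINDOW, order: int = 1) -> RawTraceSet:
    """Causal polynomial (Savitzky-Golay) smoothing, window fully in the past."""
    F = np.column_stack([
        _causal_sg(tr.F[:, i], window, order) for i in range(tr.F.shape[1])
    ])
    return replace(tr, F=F)


def preprocess(tr: RawTraceSet, outlier_k: float = 5.0,
               smooth: bool = True) -> RawTraceSet:
    """The full chain: interpolate -> bleach-correct -> outlier-remove [-> smooth].

    Kernel fitting uses the non-smoothed result (``smooth=False``); statistics
    and display use the smoothed one.
    """
    out = interpolate_missing(tr)
    out = correct_photobleach(out)
    out = remove_outliers(out, k=outlier_k)
    if smooth:
        out = smooth_causal(out)
    return out


# ----------------------------------------------------------------------
# step 5: response windows
# ----------------------------------------------------------------------

def response_window(tr: RawTraceSet, stim_time: float, neuron: int,
                    pre_s: float = PRE_WINDOW_S, post_s: float = POST_WINDOW_S) -> ResponseWindow:
    """Extract dF/F0 on [-pre, +post) s around a stimulus for one neuron.

    F0 is the mean fluorescence over the pre-stimulus interval.  Shorter
    windows at the recording edges are allowed (flagged via a log message).
    """
    dt = tr.dt
    i0 = int(round(stim_time / dt))
    lo = max(i0 - int(round(pre_s / dt)), 0)
    hi = min(i0 + int(round(post_s / dt)), tr.F.shape[0])
    if lo > i0 - int(round(pre_s / dt)) or hi < i0 + int(round(post_s / dt)):
        logger.debug("shortened response window at t=%.1f s for neuron %d", stim_time, neuron)
    seg = tr.F[lo:hi, neuron]
    t = (np.arange(lo, hi) - i0) * dt
    pre = t < 0
    post = ~pre
    if not pre.any():
        raise ValueError("no pre-stimulus samples available for baseline")
    F0 = float(seg[pre].mean())
    if F0 <= 0:
        raise ValueError(f"non-positive baseline F0={F0:.3g} for neuron {neuron}")
    values = (seg - F0) / F0
    return ResponseWindow(values=values, F0=F0, dt=dt, t=t, pre_mask=pre, post_mask=post)


def second_derivative(w: ResponseWindow, window: int = SG_WINDOW) -> np.ndarray:
    """Causal Savitzky-Golay estimate of the second time derivative of dF/F0 (1/s^2)."""
    if w.values.size < window:
        raise ValueError("window too short for second-derivative estimation")
    return _causal_sg(w.values, window, order=2, deriv=2, delta=w.dt)
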