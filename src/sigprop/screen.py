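"""Inclusion criteria: autoresponse detection and observation assembly.

A stimulation event enters the analysis only if it evoked a detectable
calcium response in the stimulated neuron itself (the autoresponse).  The
classifier requires the dF/F0 transient and its temporal second derivative to
jointly exceed a pair of thresholds for a contiguous 4 s of the post-stimulus
window; the same thresholds apply to every animal, strain, neuron and event.
Downstream traces with long contiguous gaps of missing samples are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import Recording
from .traces import (POST_WINDOW_S, RawTraceSet, ResponseWindow, preprocess,
                     response_window, second_derivative)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Joint amplitude / second-derivative thresholds for response detection.

    ``amp_thresh`` is in dF/F0 units, ``deriv_thresh`` in 1/s^2, and
    ``min_contig`` (s) is the contiguous time both must be exceeded.  The
    amplitude default reflects a response clearly above shot noise; the
    derivative default should be calibrated to ~3x the null SD of the
    second-derivative statistic on control recordings.
    """

    amp_thresh: float = 0.1
    deriv_thresh: float = 0.002
    min_contig: float = 4.0

    def __post_init__(self) -> None:
        if min(self.amp_thresh, self.deriv_thresh, self.min_contig) <= 0:
            raise ValueError("all thresholds must be positive")


def calibrate_deriv_threshold(null_deriv_sd: float, factor: float = 3.0,
                              amp_thresh: float = 0.1) -> ClassifierThresholds:
    """Thresholds with the derivative cut at ``factor`` x the null SD."""
    return ClassifierThresholds(amp_thresh=amp_thresh,
                                deriv_thresh=factor * null_deriv_sd)


@dataclass(frozen=True)
class StimEvent:
    target: int
    time: float
    duration: float
    on_target: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class Observation:
    """One (stimulus, downstream neuron) response window with inclusion flags."""

    stim: StimEvent
    downstream: int
    upstream_window: ResponseWindow | None
    downstream_window: ResponseWindow
    autoresponse_ok: bool
    trace_ok: bool

    @property
    def included(self) -> bool:
        return self.autoresponse_ok and self.trace_ok


def _contiguous_true(x: np.ndarray) -> int:
    """Length of the longest run of True."""
    best = cur = 0
    for v in x:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def detect_autoresponse(w: ResponseWindow, th: ClassifierThresholds) -> bool:
    """True iff dF/F0 > amp_thresh and |d2(dF/F0)/dt2| > deriv_thresh hold
    jointly on one contiguous post-stimulus interval of at least min_contig s.

    A post window shorter than min_contig cannot qualify (warned).
    """
    return _detect(w, th, two_sided=False)


def detect_response(w: ResponseWindow, th: ClassifierThresholds) -> bool:
    """Downstream-response variant of the classifier: |dF/F0| is thresholded,
    so inhibitory (negative-going) responses are detectable too."""
    return _detect(w, th, two_sided=True)


def _detect(w: ResponseWindow, th: ClassifierThresholds, two_sided: bool) -> bool:
    post = w.post_values
    n_req = int(round(th.min_contig / w.dt))
    if post.size < n_req:
        logger.warning("post window (%d samples) shorter than required %d; "
                       "autoresponse undetectable", post.size, n_req)
        return False
    d2 = second_derivative(w)[w.post_mask]
    amp_ok = (np.abs(post) if two_sided else post) > th.amp_thresh
    joint = amp_ok & (np.abs(d2) > th.deriv_thresh)
    return _contiguous_true(joint) >= n_req


def _max_contig_gap(mask_seg: np.ndarray) -> int:
    return _contiguous_true(mask_seg)


def response_amplitude(w: ResponseWindow) -> float:
    """Mean dF/F0 over the 30-s post-stimulus window, <dF/F0>_t."""
    return float(w.post_values.mean())


def apply_inclusion(
    rec: Recording,
    th: ClassifierThresholds,
    pre: RawTraceSet | None = None,
    raw: RawTraceSet | None = None,
    max_gap_fraction: float = 0.05,
    rid_override: bool = False,
) -> list[Observation]:
    """Assemble the observation table for one recording.

    Exclusions, counted to the log: (a) stimulation events without a detected
    autoresponse, (b) downstream traces with a contiguous missing gap longer
    than ``max_gap_fraction`` of the response window, (c) off-target events.
    ``pre`` (smoothed, preprocessed) may be supplied to avoid recomputation;
    ``raw`` optionally carries the non-smoothed traces whose windows are kept
    alongside for kernel fitting.  With ``rid_override`` windows are admitted
    without an upstream trace and |dF/F0| > 2 windows are excluded instead.
    """
    if pre is None:
        pre = preprocess(RawTraceSet(rec.F, rec.mask, rec.dt, list(rec.labels)))
    n_neurons = rec.F.shape[1]
    win_len = int(round((POST_WINDOW_S * 2) / rec.dt))
    counts = {"no_autoresponse": 0, "gap": 0, "off_target": 0, "amp_cap": 0}
    out: list[Observation] = []
    for _, row in rec.stim_log.iterrows():
        ev = StimEvent(int(row["target_index"]), float(row["time_s"]),
                       float(row["duration_s"]), bool(row["on_target"]))
        if not ev.on_target:
            counts["off_target"] += 1
            continue
        try:
            up_w = response_window(pre, ev.time, ev.target)
        except ValueError:
            up_w = None
        if up_w is not None:
            auto_ok = detect_autoresponse(up_w, th)
        else:
            auto_ok = False
        if not auto_ok:
            if not rid_override:
                counts["no_autoresponse"] += 1
                continue
            auto_ok = True  # dim-neuron policy: admit without an autoresponse
        i0 = int(round(ev.time / rec.dt))
        lo = max(i0 - int(round(POST_WINDOW_S / rec.dt)), 0)
        hi = min(i0 + int(round(POST_WINDOW_S / rec.dt)), rec.F.shape[0])
        for i in range(n_neurons):
            if i == ev.target:
                continue
            gap = _max_contig_gap(rec.mask[lo:hi, i])
            trace_ok = gap <= max_gap_fraction * win_len
            if not trace_ok:
                counts["gap"] += 1
            down_w = response_window(pre, ev.time, i)
            if rid_override and np.any(np.abs(down_w.values) > 2.0):
                counts["amp_cap"] += 1
                continue
            out.append(Observation(stim=ev, downstream=i, upstream_window=up_w,
                                   downstream_window=down_w,
                                   autoresponse_ok=auto_ok, trace_ok=trace_ok))
    logger.info("inclusion: %d observations kept; exclusions %s",
                sum(o.included for o in out), counts)
    return out
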