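"""Gait-event detection from foot-worn accelerometers.

Each foot's 3D accelerometer is processed independently.  The vertical axis,
low-pass filtered at 6 Hz, yields one "step marker" per stride (roughly
mid-swing: peaks above threshold with a minimum separation).  On the 30 Hz
filtered data, the heel strike is the first supra-threshold vertical peak
after a step marker, and the toe-off is the mean latency of the two highest
anterior-posterior peaks above threshold in the window preceding the marker.
Cycles are assembled between consecutive right-heel strikes and kept only if
the within-cycle event order and the cycle duration are plausible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class EventType(str, enum.Enum):
    STEP = "STEP"
    RHS = "RHS"
    LHS = "LHS"
    RTO = "RTO"
    LTO = "LTO"


@dataclass
class AccelTrace:
    """Per-foot acceleration (units g) with sampling rate and bout bounds."""

    vertical: np.ndarray
    anterior_posterior: np.ndarray
    fs: float
    foot: str  # "left" | "right"
    bouts: list[tuple[int, int]] | None = None  # [start, stop) sample indices

    def __post_init__(self) -> None:
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.anterior_posterior = np.asarray(self.anterior_posterior, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.vertical.shape != self.anterior_posterior.shape:
            raise ValueError("axes must have equal length")
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if self.bouts is None:
            self.bouts = [(0, len(self.vertical))]

    @property
    def n_samples(self) -> int:
        return len(self.vertical)


@dataclass
class GaitDetectionParams:
    """Detection thresholds; defaults follow the standard procedure."""

    step_threshold_g: float = 0.6
    fallback_step_threshold_g: float = 0.24
    step_min_separation_ms: float = 500.0
    heel_threshold_g: float = 0.6
    toeoff_threshold_g: float = 0.2
    toeoff_window_ms: float = 500.0
    lowpass_main_hz: float = 30.0
    lowpass_interim_hz: float = 6.0
    duration_bounds_s: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        for name in ("step_threshold_g", "heel_threshold_g", "toeoff_threshold_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.duration_bounds_s
        if not 0 < lo < hi:
            raise ValueError("duration bounds must satisfy 0 < lower < upper")


@dataclass
class GaitEvent:
    type: EventType
    latency_s: float
    foot: str


class RejectReason(str, enum.Enum):
    NONE = "none"
    ORDER = "order"
    DURATION = "duration"


@dataclass
class GaitCycle:
    """One candidate stride: RHS, LTO, LHS, RTO, next RHS (seconds)."""

    rhs: float
    lto: float | None
    lhs: float | None
    rto: float | None
    rhs_next: float
    valid: bool
    reason: RejectReason = RejectReason.NONE

    @property
    def duration(self) -> float:
        return self.rhs_next - self.rhs


@dataclass
class StrideMetrics:
    stride_times: np.ndarray
    mean_stride_s: float
    cv_pct: float  # nan (flagged) when only one valid cycle
    n_valid: int
    cv_defined: bool = True


def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def filter_accel(
    trace: AccelTrace, params: GaitDetectionParams | None = None
) -> tuple[AccelTrace, AccelTrace]:
    """Detrend per walking bout, then zero-phase Butterworth low-pass.

    Returns the 30 Hz trace (event timing) and the 6 Hz trace (step markers).
    """
    params = params or GaitDetectionParams()
    if trace.n_samples < trace.fs:  # filter warm-up
        raise ValueError("trace shorter than 1 s filter warm-up")
    out = {}
    for cutoff in (params.lowpass_main_hz, params.lowpass_interim_hz):
        axes = []
        for x in (trace.vertical, trace.anterior_posterior):
            y = x.copy()
            for b0, b1 in trace.bouts:
                if b1 - b0 > 1:
                    y[b0:b1] = signal.detrend(x[b0:b1], type="linear")
            axes.append(_lowpass(y, trace.fs, cutoff))
        out[cutoff] = AccelTrace(axes[0], axes[1], trace.fs, trace.foot, list(trace.bouts))
    return out[params.lowpass_main_hz], out[params.lowpass_interim_hz]


def detect_step_markers(
    trace_6hz: AccelTrace, params: GaitDetectionParams | None = None,
    threshold_g: float | None = None,
) -> np.ndarray:
    """Step markers: vertical peaks above threshold, min separation enforced.

    When two candidates fall within the minimum distance, the higher peak
    wins (greedy by descending height).  Restricted to walking bouts.
    Returns latencies in seconds.
    """
    params = params or GaitDetectionParams()
    thr = params.step_threshold_g if threshold_g is None else threshold_g
    dist = max(1, int(round(params.step_min_separation_ms / 1000.0 * trace_6hz.fs)))
    latencies: list[float] = []
    for b0, b1 in trace_6hz.bouts:
        seg = trace_6hz.vertical[b0:b1]
        # scipy's distance pruning is greedy by descending height
        peaks, _ = signal.find_peaks(seg, height=thr, distance=dist)
        latencies.extend((peaks + b0) / trace_6hz.fs)
    return np.asarray(sorted(latencies))


def detect_heel_strikes(
    trace_30hz: AccelTrace, step_markers: np.ndarray,
    params: GaitDetectionParams | None = None,
) -> np.ndarray:
    """First vertical peak above threshold after each step marker.

    The search is bounded by the next step marker so a heel strike cannot be
    assigned across strides.  Markers without a qualifying peak contribute
    no event.
    """
    params = params or GaitDetectionParams()
    fs = trace_30hz.fs
    peaks, _ = signal.find_peaks(trace_30hz.vertical, height=params.heel_threshold_g)
    peak_lat = peaks / fs
    out = []
    markers = np.asarray(step_markers, dtype=float)
    for i, m in enumerate(markers):
        hi = markers[i + 1] if i + 1 < len(markers) else np.inf
        cand = peak_lat[(peak_lat > m) & (peak_lat < hi)]
        if cand.size:
            out.append(cand[0])
    return np.asarray(out)


def detect_toe_offs(
    trace_30hz: AccelTrace, step_markers: np.ndarray,
    params: GaitDetectionParams | None = None,
) -> np.ndarray:
    """Toe-off = mean latency of the two highest AP peaks above threshold
    in the window preceding each step marker; fewer than two peaks => none.
    """
    params = params or GaitDetectionParams()
    fs = trace_30hz.fs
    win_s = params.toeoff_window_ms / 1000.0
    peaks, props = signal.find_peaks(
        trace_30hz.anterior_posterior, height=params.toeoff_threshold_g
    )
    peak_lat = peaks / fs
    heights = props["peak_heights"]
    out = []
    for m in np.asarray(step_markers, dtype=float):
        sel = (peak_lat >= m - win_s) & (peak_lat < m)
        if sel.sum() < 2:
            continue
        lats, hts = peak_lat[sel], heights[sel]
        top2 = np.argsort(hts)[-2:]
        out.append(float(np.mean(lats[top2])))
    return np.asarray(sorted(out))


def assemble_gait_cycles(
    events_left: list[GaitEvent], events_right: list[GaitEvent],
    params: GaitDetectionParams | None = None,
) -> list[GaitCycle]:
    """Build candidate cycles between consecutive RHS events and validate.

    A cycle is valid iff the events occur strictly in the order
    RHS < LTO < LHS < RTO < next RHS and the duration lies within the
    plausibility bounds.  Missing in-between events count as order
    violations.  Duration is checked first so that a too-long window is not
    blamed on the (likely unrelated) events that drifted into it.
    """
    params = params or GaitDetectionParams()
    lo, hi = params.duration_bounds_s
    rhs = sorted(e.latency_s for e in events_right if e.type is EventType.RHS)
    rto = np.asarray(sorted(e.latency_s for e in events_right if e.type is EventType.RTO))
    lhs = np.asarray(sorted(e.latency_s for e in events_left if e.type is EventType.LHS))
    lto = np.asarray(sorted(e.latency_s for e in events_left if e.type is EventType.LTO))

    def first_in(arr: np.ndarray, t0: float, t1: float) -> float | None:
        sel = arr[(arr > t0) & (arr < t1)]
        return float(sel[0]) if sel.size else None

    cycles: list[GaitCycle] = []
    for a, b in zip(rhs[:-1], rhs[1:]):
        c_lto = first_in(lto, a, b)
        c_lhs = first_in(lhs, a, b)
        c_rto = first_in(rto, a, b)
        dur = b - a
        if not (lo <= dur <= hi):
            cycles.append(GaitCycle(a, c_lto, c_lhs, c_rto, b, False, RejectReason.DURATION))
            continue
        seq = [a, c_lto, c_lhs, c_rto, b]
        if any(v is None for v in seq) or any(
            seq[i] >= seq[i + 1] for i in range(4)  # type: ignore[operator]
        ):
            cycles.append(GaitCycle(a, c_lto, c_lhs, c_rto, b, False, RejectReason.ORDER))
            continue
        cycles.append(GaitCycle(a, c_lto, c_lhs, c_rto, b, True))
    return cycles


def coefficient_of_variation(times: np.ndarray) -> float:
    """CV in percent: 100 * sample SD / mean (unit-scale invariant)."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("CV requires at least 2 values")
    return 100.0 * float(np.std(times, ddof=1)) / float(np.mean(times))


def stride_metrics(cycles: list[GaitCycle]) -> StrideMetrics:
    """Stride times of valid cycles; CV = 100 * sample SD / mean."""
    times = np.asarray([c.duration for c in cycles if c.valid])
    if times.size == 0:
        raise ValueError("no valid gait cycles: stride metrics undefined")
    mean = float(np.mean(times))
    if times.size == 1:
        return StrideMetrics(times, mean, float("nan"), 1, cv_defined=False)
    return StrideMetrics(times, mean, coefficient_of_variation(times), int(times.size))


def detect_foot_events(
    trace: AccelTrace, params: GaitDetectionParams | None = None,
    step_threshold_g: float | None = None,
) -> list[GaitEvent]:
    """Full per-foot chain: filter -> step markers -> heel strikes + toe-offs."""
    params = params or GaitDetectionParams()
    t30, t6 = filter_accel(trace, params)
    markers = detect_step_markers(t6, params, threshold_g=step_threshold_g)
    hs = detect_heel_strikes(t30, markers, params)
    to = detect_toe_offs(t30, markers, params)
    hs_t = EventType.RHS if trace.foot == "right" else EventType.LHS
    to_t = EventType.RTO if trace.foot == "right" else EventType.LTO
    events = [GaitEvent(EventType.STEP, t, trace.foot) for t in markers]
    events += [GaitEvent(hs_t, t, trace.foot) for t in hs]
    events += [GaitEvent(to_t, t, trace.foot) for t in to]
    events.sort(key=lambda e: e.latency_s)
    return events
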