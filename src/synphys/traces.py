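"""Fluorescence time-series quantification.

Operations on ROI-mean fluorescence traces sampled at a fixed interval
(100 ms by default): background subtraction and dF/F normalization,
boxcar smoothing, baseline statistics (including a histogram-mode
estimator used as the GCaMP baseline), responder classification against
a mean + k*SD threshold, window metrics (AUC, extrema), and the
pre-stimulus motion-artifact exclusion used for GCaMP recordings.

Analysis windows are half-open intervals [start, end) in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "TimeSeriesTrace",
    "WindowSpec",
    "ResponderCall",
    "DegenerateBaselineError",
    "delta_f_over_f",
    "moving_average",
    "baseline_stats",
    "above_background_gate",
    "classify_responder",
    "window_metric",
    "gcamp_prestimulus_exclusion",
    "normalize_expression",
    "rank_traces",
]

_TIME_TOL = 1e-9


class DegenerateBaselineError(ValueError):
    """Baseline fluorescence is non-positive; dF/F is undefined."""


@dataclass
class WindowSpec:
    """Half-open analysis window [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must be < end {self.end}")

    def mask(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.start) & (t < self.end)


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled fluorescence (F) or dF/F trace for one ROI.

    Exactly one of ``F`` and ``dff`` is the primary signal.  ``F_bg`` is a
    per-sample background trace used for background subtraction.
    """

    trace_id: str
    t: np.ndarray
    F: np.ndarray | None = None
    dff: np.ndarray | None = None
    F_bg: np.ndarray | None = None
    genotype: str = ""
    excitation_intensity: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size < 2:
            raise ValueError(f"trace {self.trace_id}: needs >= 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError(f"trace {self.trace_id}: time not strictly increasing")
        if np.ptp(dt) > _TIME_TOL:
            raise ValueError(f"trace {self.trace_id}: non-uniform sampling interval")
        if self.F is None and self.dff is None:
            raise ValueError(f"trace {self.trace_id}: one of F or dff required")
        for name in ("F", "dff", "F_bg"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.t.shape:
                    raise ValueError(f"trace {self.trace_id}: {name} length mismatch")
                setattr(self, name, v)
        if self.F is not None and np.any(self.F < 0):
            raise ValueError(f"trace {self.trace_id}: raw F must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def signal(self) -> np.ndarray:
        """Primary signal: dff when populated, else F."""
        return self.dff if self.dff is not None else self.F

    def window_values(self, window: WindowSpec, which: str = "signal") -> np.ndarray:
        x = self.signal if which == "signal" else getattr(self, which)
        vals = x[window.mask(self.t)]
        if vals.size == 0:
            raise ValueError(
                f"trace {self.trace_id}: window [{window.start}, {window.end}) "
                "contains no samples"
            )
        return vals


@dataclass
class ResponderCall:
    """Outcome of responder classification for one trace."""

    trace_id: str
    above_background: bool
    responder: bool
    peak_value: float
    peak_time: float
    reason: Literal["none", "below_background", "below_threshold"] = "none"

    def __post_init__(self) -> None:
        if self.responder and not self.above_background:
            raise ValueError("responder implies above_background")


def _background_subtracted(trace: TimeSeriesTrace) -> np.ndarray:
    if trace.F is None:
        raise ValueError(f"trace {trace.trace_id}: raw F required")
    F = trace.F
    if trace.F_bg is not None:
        F = F - trace.F_bg
    return F


def delta_f_over_f(trace: TimeSeriesTrace, baseline: WindowSpec) -> TimeSeriesTrace:
    """Normalize a raw-F trace to dF/F against its baseline-window mean.

    Background is subtracted sample-wise first when ``F_bg`` is present;
    F0 is the mean of background-subtracted F over ``baseline``.
    Raises :class:`DegenerateBaselineError` when F0 <= 0.
    """
    Fp = _background_subtracted(trace)
    mask = baseline.mask(trace.t)
    if mask.sum() < 2:
        raise ValueError(
            f"trace {trace.trace_id}: baseline window needs >= 2 samples"
        )
    F0 = float(Fp[mask].mean())
    if F0 <= 0:
        raise DegenerateBaselineError(
            f"trace {trace.trace_id}: baseline mean {F0:.6g} <= 0"
        )
    return replace(trace, dff=(Fp - F0) / F0)


def _boxcar_samples(width: float, dt: float) -> int:
    if width < dt - _TIME_TOL:
        raise ValueError(f"filter width {width} s < sampling interval {dt} s")
    n = int(np.floor(width / dt + _TIME_TOL))
    if n % 2 == 0:
        n -= 1
    return max(n, 1)

def moving_average(trace: TimeSeriesTrace, width: float) -> TimeSeriesTrace:
    """Centered boxcar filter of the primary signal.

    The window holds floor(width/dt) samples, rounded down to the nearest
    odd count >= 1, and shrinks symmetrically at the trace edges so the
    output has the input's length.
    """
    n = _boxcar_samples(width, trace.dt)
    x = trace.signal
    half = n // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(x.size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, x.size - 1)
    smoothed = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    if trace.dff is not None:
        return replace(trace, dff=smoothed)
    return replace(trace, F=smoothed)


def baseline_stats(
    trace: TimeSeriesTrace, window: WindowSpec, mode_bin: float = 0.01
) -> tuple[float, float, float]:
    """Mean, sample SD (n-1), and histogram mode of dF/F over a window.

    The mode is the center of the most populated bin of width ``mode_bin``;
    bin centers are aligned to the window's data minimum so constant data
    returns its own value, and ties resolve to the lowest bin.
    """
    if trace.dff is None:
        raise ValueError(f"trace {trace.trace_id}: dff required")
    if mode_bin <= 0:
        raise ValueError("mode_bin must be > 0")
    vals = trace.window_values(window, "dff")
    if vals.size < 2:
        raise ValueError(f"trace {trace.trace_id}: window needs >= 2 samples")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    lo, hi = float(vals.min()), float(vals.max())
    # bin centers at lo, lo+bin, ...; edges shifted half a bin below lo
    nbins = int(np.floor((hi - lo) / mode_bin + 0.5)) + 1
    edges = lo - mode_bin / 2 + mode_bin * np.arange(nbins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    mode = lo + mode_bin * int(np.argmax(counts))
    return mean, sd, mode


def above_background_gate(
    trace: TimeSeriesTrace,
    background_trace: TimeSeriesTrace,
    window: WindowSpec,
    k: float = 3.0,
) -> bool:
    """Keep a trace only when its baseline F clears the background level.

    Returns True (keep) iff mean F over ``window`` is strictly greater
    than mean + k*SD of the background trace over the same window; the
    boundary case (equality) is excluded.
    """
    f_mean = float(trace.window_values(window, "F").mean())
    bg = background_trace.window_values(window, "F" if background_trace.F is not None else "signal")
    return f_mean > float(bg.mean()) + k * float(bg.std(ddof=1))


def classify_responder(
    trace: TimeSeriesTrace,
    baseline: WindowSpec,
    response: WindowSpec,
    filter_width: float = 1.0,
    k: float = 3.0,
    direction: Literal["increase", "decrease"] = "increase",
    above_background: bool = True,
) -> ResponderCall:
    """Call a trace a responder from its smoothed dF/F.

    The trace is boxcar-smoothed with ``filter_width``; it is a responder
    when the smoothed extremum over ``response`` clears the smoothed
    baseline mean by more than k baseline SDs (below, for decreases).
    ``above_background`` carries the upstream background-gate outcome: a
    trace that failed it is never a responder.
    """
    if trace.dff is None:
        raise ValueError(f"trace {trace.trace_id}: dff required")
    smoothed = moving_average(trace, filter_width)
    b = smoothed.window_values(baseline, "dff")
    b_mean, b_sd = float(b.mean()), float(b.std(ddof=1))
    mask = response.mask(smoothed.t)
    if not mask.any():
        raise ValueError(f"trace {trace.trace_id}: empty response window")
    seg = smoothed.dff[mask]
    seg_t = smoothed.t[mask]
    if direction == "increase":
        i = int(np.argmax(seg))
        hit = seg[i] > b_mean + k * b_sd
    else:
        i = int(np.argmin(seg))
        hit = seg[i] < b_mean - k * b_sd
    if not above_background:
        return ResponderCall(trace.trace_id, False, False, float(seg[i]),
                             float(seg_t[i]), "below_background")
    return ResponderCall(
        trace.trace_id, True, bool(hit), float(seg[i]), float(seg_t[i]),
        "none" if hit else "below_threshold",
    )


def window_metric(
    trace: TimeSeriesTrace, window: WindowSpec, kind: Literal["auc", "max", "min"]
) -> float:
    """AUC (trapezoid, dF/F*s) or extremum of raw (unfiltered) dF/F in a window.

    The AUC integrates over the closed interval [start, end] so that it
    is exactly additive across adjacent windows sharing a boundary
    sample; extrema use the half-open window like every other operation.
    """
    if trace.dff is None:
        raise ValueError(f"trace {trace.trace_id}: dff required")
    if kind == "auc":
        mask = (trace.t >= window.start) & (trace.t <= window.end + _TIME_TOL)
        vals = trace.dff[mask]
        if vals.size == 0:
            raise ValueError(f"trace {trace.trace_id}: empty window")
        return float(np.trapezoid(vals, trace.t[mask]))
    mask = window.mask(trace.t)
    vals = trace.dff[mask]
    if vals.size == 0:
        raise ValueError(f"trace {trace.trace_id}: empty window")
    if kind == "max":
        return float(vals.max())
    if kind == "min":
        return float(vals.min())
    raise ValueError(f"unknown metric kind {kind!r}")


def gcamp_prestimulus_exclusion(
    traces: Sequence[TimeSeriesTrace],
    baseline: WindowSpec | None = None,
    filter_width: float = 0.5,
    k: float = 5.0,
    mode_bin: float = 0.01,
) -> dict[str, bool]:
    """Flag traces with large pre-stimulus transients (motion artifacts).

    Traces are grouped by genotype.  Each trace is smoothed with a 0.5 s
    boxcar; the genotype's pooled SD is the mean of the per-trace baseline
    SDs of the smoothed traces.  A trace is excluded when its smoothed
    baseline maximum exceeds its own baseline mode + k * pooled SD.  The
    mode replaces the mean (and the pooled SD the per-trace SD) because a
    trace with a large transient inflates both its own mean and SD.

    Returns ``{trace_id: keep}`` with True meaning the trace is retained.
    """
    if baseline is None:
        baseline = WindowSpec(0.0, 10.0)
    groups: dict[str, list[TimeSeriesTrace]] = {}
    for tr in traces:
        groups.setdefault(tr.genotype, []).append(tr)
    keep: dict[str, bool] = {}
    for members in groups.values():
        smoothed = [moving_average(tr, filter_width) for tr in members]
        sds = []
        for sm in smoothed:
            b = sm.window_values(baseline, "dff")
            if b.size < 2:
                raise ValueError(f"trace {sm.trace_id}: single-sample baseline")
            sds.append(float(b.std(ddof=1)))
        pooled_sd = float(np.mean(sds))
        for sm in smoothed:
            _, _, mode = baseline_stats(sm, baseline, mode_bin)
            b_max = float(sm.window_values(baseline, "dff").max())
            keep[sm.trace_id] = not (b_max > mode + k * pooled_sd)
    return keep


def normalize_expression(
    trace: TimeSeriesTrace, baseline: WindowSpec, excitation_intensity: float | None = None
) -> float:
    """Mean background-subtracted baseline F per unit excitation intensity.

    Used to compare sensor expression levels between cells imaged at
    different illumination settings.
    """
    intensity = (
        excitation_intensity
        if excitation_intensity is not None
        else trace.excitation_intensity
    )
    if intensity is None or intensity <= 0:
        raise ValueError("excitation intensity must be > 0")
    Fp = _background_subtracted(trace)
    return float(Fp[baseline.mask(trace.t)].mean()) / intensity


def rank_traces(
    traces: Iterable[TimeSeriesTrace], window: WindowSpec
) -> list[TimeSeriesTrace]:
    """Stable descending sort by mean dF/F over a window (ties keep input order)."""
    traces = list(traces)
    means = [-float(tr.window_values(window, "dff").mean()) for tr in traces]
    order = np.argsort(means, kind="stable")
    return [traces[i] for i in order]
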