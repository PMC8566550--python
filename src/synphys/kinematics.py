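"""Worm-track kinematics for CO2-evoked locomotor responses.

Multi-worm tracker output (centroid positions in pixels over time) is
quality-controlled, converted to instantaneous speed and heading-change
series, and summarized as population time series of mean speed and
high-angle-turn probability.  Stimulus-locked statistics follow the
field's convention: locate the population extremum inside each stimulus
window, take an asymmetric window around it (-15/+17 s), and average the
per-sample metric over that window for every track spanning it.  The
chemotaxis avoidance index summarizes endpoint counts from two-sided
arena assays.

Unlike the half-open trace windows, behavior windows are inclusive at
both ends (a track "spanning 465-497 s" includes both endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Track",
    "PixelScale",
    "StimulusSchedule",
    "PopulationSeries",
    "AvoidanceCount",
    "TURN_THRESHOLD_DEG_PER_S",
    "speed_series",
    "heading_change_series",
    "detect_turns",
    "filter_tracks",
    "population_series",
    "extremum_window",
    "per_track_window_mean",
    "avoidance_index",
]

#: High-angle turn criterion: direction change >= 50 deg/s (inclusive).
TURN_THRESHOLD_DEG_PER_S = 50.0

#: Track-QC speed threshold in tracker units, with its micron equivalent.
MIN_TRACK_SPEED_PX_PER_S = 1.17
MIN_TRACK_SPEED_UM_PER_S = 38.15


@dataclass(frozen=True)
class PixelScale:
    """Camera calibration; the default reproduces 1.17 px/s = 38.15 um/s."""

    microns_per_pixel: float = MIN_TRACK_SPEED_UM_PER_S / MIN_TRACK_SPEED_PX_PER_S

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")


@dataclass
class Track:
    """One worm's centroid positions over time (pixels)."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    genotype: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 samples")
        if self.x.shape != self.t.shape or self.y.shape != self.t.shape:
            raise ValueError(f"track {self.track_id}: coordinate length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id}: time not strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def spans(self, start: float, end: float) -> bool:
        """Inclusive spanning: the track covers [start, end] entirely."""
        return self.t[0] <= start and self.t[-1] >= end


@dataclass(frozen=True)
class StimulusSchedule:
    """Named stimulus windows (inclusive endpoints, seconds), ordered in time.

    ``prestimulus`` is the fixed quantification window used for the
    pre-stimulus period (465-497 s by default).
    """

    windows: tuple[tuple[str, float, float], ...]
    prestimulus: tuple[float, float] = (465.0, 497.0)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for name, start, end in self.windows:
            if start >= end:
                raise ValueError(f"window {name}: start must be < end")
            if start < prev_end:
                raise ValueError(f"window {name}: windows overlap or are unordered")
            prev_end = end


@dataclass
class PopulationSeries:
    """Per-time-point population statistics over tracks present at that time."""

    t: np.ndarray
    mean_speed: np.ndarray  # um/s; NaN where no track present
    turn_probability: np.ndarray  # fraction of present tracks turning; NaN if none
    n_tracks: np.ndarray
    n_heading: np.ndarray = field(default=None)  # tracks with a defined turn flag


def speed_series(
    track: Track, scale: PixelScale = PixelScale()
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous speed in um/s, assigned to the later sample of each step.

    Returns ``(t, speed)`` of length ``len(track) - 1``.
    """
    dt = np.diff(track.t)
    if np.any(dt == 0):
        raise ValueError(f"track {track.track_id}: zero time step")
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    return track.t[1:], scale.microns_per_pixel * disp / dt


def heading_change_series(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Absolute heading change rate (deg/s) between consecutive displacement steps.

    Heading is the direction of each displacement vector; changes are
    wrapped to [0, 180] degrees and divided by the step duration.  Frames
    with zero displacement inherit the previous heading; steps with no
    previous defined heading yield NaN.  Returns ``(t, change)`` of
    length ``len(track) - 2``, timestamped at the later sample.
    """
    if track.t.size < 3:
        raise ValueError(f"track {track.track_id}: >= 3 samples required")
    dx, dy = np.diff(track.x), np.diff(track.y)
    moving = (dx != 0) | (dy != 0)
    heading = np.degrees(np.arctan2(dy, dx))
    # carry the last defined heading through stationary frames
    last = np.nan
    for i in range(heading.size):
        if moving[i]:
            last = heading[i]
        else:
            heading[i] = last
    dt = np.diff(track.t)[1:]
    dh = np.abs(np.diff(heading))
    dh = np.where(dh > 180.0, 360.0 - dh, dh)  # wrap to [0, 180]
    return track.t[2:], dh / dt


def detect_turns(
    heading_change: np.ndarray, threshold: float = TURN_THRESHOLD_DEG_PER_S
) -> np.ndarray:
    """High-angle turn flags: direction change >= threshold (inclusive).

    NaN entries (undefined heading) are never turns.
    """
    with np.errstate(invalid="ignore"):
        return np.asarray(heading_change) >= threshold


def filter_tracks(
    tracks: Iterable[Track],
    min_duration: float = 30.0,
    min_mean_speed_px: float = MIN_TRACK_SPEED_PX_PER_S,
    scale: PixelScale = PixelScale(),
) -> list[Track]:
    """Exclude non-worm objects: short tracks and slow (debris) tracks.

    Keeps tracks lasting at least ``min_duration`` seconds whose *mean*
    instantaneous speed is at least ``min_mean_speed_px`` pixels/s.  (A
    minimum-instantaneous-speed reading would discard real worms, which
    pause; the mean-speed reading is used throughout.)
    """
    kept = []
    for tr in tracks:
        if tr.duration < min_duration:
            continue
        _, v = speed_series(tr, scale)
        if v.mean() / scale.microns_per_pixel < min_mean_speed_px:
            continue
        kept.append(tr)
    return kept


def population_series(
    tracks: Sequence[Track],
    time_grid: np.ndarray,
    scale: PixelScale = PixelScale(),
    turn_threshold: float = TURN_THRESHOLD_DEG_PER_S,
    match_tol: float = 1e-6,
) -> PopulationSeries:
    """Mean speed and turn probability across tracks present at each grid time.

    Tracks are matched to grid points by timestamp (within ``match_tol``
    seconds); points covered by no track yield NaN.  Turn probability at a
    time point is the fraction of tracks with a defined heading change
    there whose change meets the turn criterion.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    n = time_grid.size
    speed_sum = np.zeros(n)
    speed_n = np.zeros(n, dtype=int)
    turn_sum = np.zeros(n)
    turn_n = np.zeros(n, dtype=int)

    for tr in tracks:
        ts, v = speed_series(tr, scale)
        th, h = heading_change_series(tr)
        flags = detect_turns(h, turn_threshold)
        idx = np.searchsorted(time_grid, ts)
        for j, (tv, vv) in enumerate(zip(ts, v)):
            i = idx[j]
            for cand in (i - 1, i):
                if 0 <= cand < n and abs(time_grid[cand] - tv) <= match_tol:
                    speed_sum[cand] += vv
                    speed_n[cand] += 1
                    break
        idx = np.searchsorted(time_grid, th)
        for j, tv in enumerate(th):
            if np.isnan(h[j]):
                continue
            i = idx[j]
            for cand in (i - 1, i):
                if 0 <= cand < n and abs(time_grid[cand] - tv) <= match_tol:
                    turn_sum[cand] += flags[j]
                    turn_n[cand] += 1
                    break

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_speed = np.where(speed_n > 0, speed_sum / np.maximum(speed_n, 1), np.nan)
        turn_prob = np.where(turn_n > 0, turn_sum / np.maximum(turn_n, 1), np.nan)
    return PopulationSeries(time_grid, mean_speed, turn_prob, speed_n, turn_n)


def extremum_window(
    series_t: np.ndarray,
    series_values: np.ndarray,
    stimulus_window: tuple[float, float],
    mode: Literal["min_speed", "max_turn"],
    before: float = 15.0,
    after: float = 17.0,
) -> tuple[float, float]:
    """Quantification window around the population extremum in a stimulus window.

    Locates t_min (speed) or t_max (turn probability) within the stimulus
    window, earliest time on ties, and returns the inclusive window
    [t* - before, t* + after].
    """
    series_t = np.asarray(series_t, dtype=float)
    series_values = np.asarray(series_values, dtype=float)
    mask = (series_t >= stimulus_window[0]) & (series_t <= stimulus_window[1])
    mask &= np.isfinite(series_values)
    if not mask.any():
        raise ValueError("stimulus window contains no defined series points")
    seg_t, seg_v = series_t[mask], series_values[mask]
    i = int(np.argmin(seg_v)) if mode == "min_speed" else int(np.argmax(seg_v))
    t_star = float(seg_t[i])
    return t_star - before, t_star + after


def per_track_window_mean(
    tracks: Iterable[Track],
    window: tuple[float, float],
    metric: Literal["speed", "turn"],
    scale: PixelScale = PixelScale(),
    turn_threshold: float = TURN_THRESHOLD_DEG_PER_S,
) -> dict[str, float]:
    """Mean per-sample speed or turn fraction over a window, per spanning track.

    A track spans the window iff it starts at or before the window start
    and ends at or after the window end; others are omitted.  Sample
    inclusion in the window is inclusive at both ends.
    """
    start, end = window
    out: dict[str, float] = {}
    for tr in tracks:
        if not tr.spans(start, end):
            continue
        if metric == "speed":
            ts, v = speed_series(tr, scale)
        else:
            ts, h = heading_change_series(tr)
            v = detect_turns(h, turn_threshold).astype(float)
            v[np.isnan(h)] = np.nan
        m = (ts >= start) & (ts <= end) & np.isfinite(v)
        if not m.any():
            continue
        out[tr.track_id] = float(v[m].mean())
    return out


@dataclass(frozen=True)
class AvoidanceCount:
    """Endpoint counts of one chemotaxis trial: worms on the air vs CO2 side."""

    n_air: int
    n_co2: int

    def __post_init__(self) -> None:
        if self.n_air < 0 or self.n_co2 < 0:
            raise ValueError("counts must be >= 0")
        if self.n_air + self.n_co2 == 0:
            raise ValueError("at least one worm required")


def avoidance_index(counts: AvoidanceCount) -> float:
    """AI = (n_air - n_co2) / (n_air + n_co2), in [-1, 1]; +1 = full avoidance."""
    return (counts.n_air - counts.n_co2) / (counts.n_air + counts.n_co2)
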