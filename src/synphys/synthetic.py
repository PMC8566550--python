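"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the study's recording conditions: dual-calibration
synaptopHluorin traces built from the forward calibration model with
first-order response kinetics and i.i.d. Gaussian noise; KCl/GCaMP-style
evoked dF/F traces with optional pre-stimulus motion transients; worm
tracks as correlated random walks with a stimulus-evoked slow regime and
Poisson turn events; and binomial chemotaxis endpoint counts.

All generators are deterministic given (seed, parameters): the same
config yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import AvoidanceCount, PixelScale, StimulusSchedule, Track
from .traces import TimeSeriesTrace
from .vesicle_ph import Constants, DEFAULT_CONSTANTS, forward_calibration

__all__ = [
    "SimulationConfig",
    "CalibrationExperiment",
    "gen_calibration_experiment",
    "gen_response_trace",
    "gen_tracks",
    "gen_chemotaxis_counts",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared generator settings.

    dt: sampling interval, seconds (0.1 s matches the 100 ms camera frame).
    noise_sd: Gaussian noise SD in dF/F units; 0.02 makes the 3-SD
        responder gates nontrivial without overwhelming real responses.
    tau: first-order response time constant, seconds (0 = instantaneous).
    """

    seed: int = 0
    dt: float = 0.1
    noise_sd: float = 0.02
    tau: float = 1.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _first_order_profile(
    t: np.ndarray, start: float, end: float, amplitude: float, tau: float
) -> np.ndarray:
    """Amplitude reached with first-order kinetics inside [start, end), decaying after."""
    y = np.zeros_like(t)
    on = (t >= start) & (t < end)
    if tau <= 0:
        y[on] = amplitude
        return y
    y[on] = amplitude * (1 - np.exp(-(t[on] - start) / tau))
    after = t >= end
    y_end = amplitude * (1 - np.exp(-(end - start) / tau))
    y[after] = y_end * np.exp(-(t[after] - end) / tau)
    return y


@dataclass
class CalibrationExperiment:
    """Paired NH4Cl and MES recordings of one punctum, with ground truth.

    The two perturbations are applied in separate recordings of different
    lengths (NH4Cl: 20 s saline / 40 s NH4Cl / 20 s saline; MES: 20 s
    saline / 60 s MES / 120 s saline), each with its own time base.
    """

    nh4_trace: TimeSeriesTrace
    mes_trace: TimeSeriesTrace
    truth: dict = field(default_factory=dict)


def gen_calibration_experiment(
    pH_true: float,
    SF_true: float,
    constants: Constants = DEFAULT_CONSTANTS,
    config: SimulationConfig = SimulationConfig(),
    punctum_id: str = "punctum",
    genotype: str = "wild_type",
    F0: float = 100.0,
    F_bg: float = 10.0,
) -> CalibrationExperiment:
    """Simulate a punctum's NH4Cl and MES calibration recordings.

    The NH4Cl segment plateaus at dF/F = gamma(pH_true, SF_true) and the
    MES segment at -epsilon(pH_true, SF_true), approached with
    first-order kinetics; Gaussian noise (config.noise_sd, dF/F units) is
    added to the raw fluorescence.  Baseline fluorescence is F0 above a
    constant background F_bg.
    """
    if not constants.pH_acid < pH_true < constants.pH_external:
        raise ValueError(f"pH_true {pH_true} outside ({constants.pH_acid}, "
                         f"{constants.pH_external})")
    if not 0 < SF_true < 1:
        raise ValueError(f"SF_true {SF_true} outside (0, 1)")
    gamma, epsilon = forward_calibration(pH_true, SF_true, constants)
    rng = config.rng(stream=1)

    def make(trace_id: str, total: float, start: float, end: float,
             amplitude: float) -> TimeSeriesTrace:
        t = np.arange(0.0, total, config.dt)
        dff = _first_order_profile(t, start, end, amplitude, config.tau)
        F = F_bg + F0 * (1 + dff) + F0 * config.noise_sd * rng.standard_normal(t.size)
        return TimeSeriesTrace(
            trace_id=trace_id, t=t, F=np.clip(F, 0, None),
            F_bg=np.full_like(t, F_bg), genotype=genotype,
        )

    nh4 = make(f"{punctum_id}_nh4cl", 80.0, 20.0, 60.0, gamma)
    mes = make(f"{punctum_id}_mes", 200.0, 20.0, 80.0, -epsilon)
    truth = {"pH": pH_true, "SF": SF_true, "gamma": gamma, "epsilon": epsilon}
    return CalibrationExperiment(nh4, mes, truth)


def gen_response_trace(
    amplitude: float,
    onset: float = 10.0,
    config: SimulationConfig = SimulationConfig(),
    duration: float = 30.0,
    stim_duration: float = 5.0,
    transient: tuple[float, float] | None = None,
    trace_id: str = "trace",
    genotype: str = "wild_type",
) -> TimeSeriesTrace:
    """A dF/F trace with a stimulus-evoked response of known amplitude.

    Baseline is zero-mean Gaussian noise; the response rises with
    first-order kinetics at ``onset`` and decays after
    ``onset + stim_duration``.  ``transient=(amp, time)`` injects a 0.3 s
    Gaussian bump before the stimulus to exercise the pre-stimulus
    artifact exclusion.
    """
    if not 0 <= onset < duration:
        raise ValueError("onset must fall within the trace")
    rng = config.rng(stream=2)
    t = np.arange(0.0, duration, config.dt)
    dff = _first_order_profile(t, onset, onset + stim_duration, amplitude, config.tau)
    if transient is not None:
        amp, t0 = transient
        dff = dff + amp * np.exp(-0.5 * ((t - t0) / 0.3) ** 2)
    dff = dff + config.noise_sd * rng.standard_normal(t.size)
    return TimeSeriesTrace(trace_id=trace_id, t=t, dff=dff, genotype=genotype)


def gen_tracks(
    n_worms: int,
    v_baseline: float,
    v_stimulus: float,
    turn_rate_baseline: float,
    turn_rate_stimulus: float,
    schedule: StimulusSchedule,
    config: SimulationConfig = SimulationConfig(),
    duration: float = 300.0,
    dt: float = 1.0,
    scale: PixelScale = PixelScale(),
    heading_diffusion_deg: float = 8.0,
    speed_cv: float = 0.1,
    stagger_fraction: float = 0.3,
    genotype: str = "wild_type",
) -> list[Track]:
    """Correlated-random-walk worm tracks with a stimulus-evoked slow regime.

    Speeds are in um/s (converted to pixel steps through ``scale``); the
    active regime (baseline vs stimulus speed, baseline vs stimulus turn
    rate) switches inside the schedule's stimulus windows.  Turn events
    are Poisson with the active rate and jump the heading by at least 60
    degrees; between turns the heading diffuses slowly.  A
    ``stagger_fraction`` of tracks start late or end early to exercise
    window-spanning rules.
    """
    rng = config.rng(stream=3)
    grid = np.arange(0.0, duration + dt / 2, dt)

    def in_stimulus(time: float) -> bool:
        return any(s <= time <= e for _, s, e in schedule.windows)

    tracks: list[Track] = []
    for w in range(n_worms):
        if rng.random() < stagger_fraction:
            i0 = int(rng.integers(0, max(1, grid.size // 5)))
            i1 = int(rng.integers(grid.size - max(1, grid.size // 5), grid.size))
        else:
            i0, i1 = 0, grid.size - 1
        t = grid[i0 : i1 + 1]
        n = t.size
        x = np.empty(n)
        y = np.empty(n)
        x[0], y[0] = rng.uniform(0, 2000, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        for i in range(1, n):
            stim = in_stimulus(t[i])
            v = v_stimulus if stim else v_baseline
            rate = turn_rate_stimulus if stim else turn_rate_baseline
            if rng.random() < 1 - np.exp(-rate * dt):
                jump = np.radians(rng.uniform(60.0, 180.0)) * rng.choice([-1.0, 1.0])
                heading += jump
            else:
                heading += np.radians(heading_diffusion_deg) * rng.standard_normal()
            step_um = v * dt * max(0.0, 1 + speed_cv * rng.standard_normal())
            step_px = step_um / scale.microns_per_pixel
            x[i] = x[i - 1] + step_px * np.cos(heading)
            y[i] = y[i - 1] + step_px * np.sin(heading)
        tracks.append(Track(track_id=f"worm{w:03d}", t=t, x=x, y=y, genotype=genotype))
    return tracks


def gen_chemotaxis_counts(
    n_worms: int,
    p_air: float,
    n_trials: int,
    config: SimulationConfig = SimulationConfig(),
) -> list[AvoidanceCount]:
    """Binomial endpoint counts; expected avoidance index is 2*p_air - 1."""
    if not 0 <= p_air <= 1:
        raise ValueError("p_air must be in [0, 1]")
    rng = config.rng(stream=4)
    counts = []
    for _ in range(n_trials):
        n_air = int(rng.binomial(n_worms, p_air))
        counts.append(AvoidanceCount(n_air=n_air, n_co2=n_worms - n_air))
    return counts
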