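"""Vesicular pH and probe surface fraction from pHluorin calibrations.

Superecliptic pHluorin fluorescence tracks its deprotonated fraction,
f(pH) = 1 / (1 + 10^(pK - pH)), with apparent pK = 7.18.  A punctum's
signal mixes probe inside vesicles at lumenal pH with probe on the
plasma membrane at external pH 7.2; the surface fraction SF is the
membrane share.  Two calibration perturbations constrain (pH, SF):

* NH4Cl collapses the vesicular pH gradient, bringing all probe to
  external pH; the fractional signal increase is gamma.
* MES at pH 5.5 quenches the surface-exposed probe; the fractional
  signal decrease is epsilon.

Each measurement yields SF as a function of the unknown lumenal pH:

    SF_eps(pH) = eps / (1 - C(pH) + (1 - eps) * A(pH))
    SF_gam(pH) = (A(pH) - gamma) / (A(pH) * (gamma + 1))

with A(pH) = (10^(pK-pH) - 10^(pK-7.2)) / (1 + 10^(pK-7.2)) and
C(pH) = (1 + 10^(pK-pH)) / (1 + 10^(pK-5.5)).  The intersection of the
two curves gives the punctum's lumenal pH and SF.  Solutions below
pH 5.0 fall outside the probe's dynamic range and are excluded.

The module also evaluates the exocytosis correction factor delta, the
predicted fractional signal increase when a vesicle's pH jumps from its
baseline pH_a to 7.2 during fusion; the ratio delta_ref/delta_mut
rescales depolarization-evoked signals so genotypes with different
resting vesicular pH become comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .traces import TimeSeriesTrace, WindowSpec, moving_average

__all__ = [
    "Constants",
    "CalibrationMeasurement",
    "PHSolution",
    "DeltaAdjustment",
    "measure_gamma",
    "measure_epsilon",
    "sf_from_gamma",
    "sf_from_epsilon",
    "forward_calibration",
    "solve_ph_sf",
    "delta_factor",
    "delta_ratio",
    "adjust_exocytosis_signal",
    "summarize_genotype",
]


@dataclass(frozen=True)
class Constants:
    """Calibration constants for superecliptic pHluorin.

    pK: apparent pK of the probe (7.18).
    pH_external: pH of the external/NH4Cl saline (7.2; also the
        cytoplasmic pH the probe reaches when the gradient collapses).
    pH_acid: pH of the MES quench solution (5.5).
    pH_floor: lower limit of the probe's dynamic range; solutions below
        it are excluded.
    """

    pK: float = 7.18
    pH_external: float = 7.2
    pH_acid: float = 5.5
    pH_floor: float = 5.0

    def __post_init__(self) -> None:
        if not self.pH_acid < self.pH_external:
            raise ValueError("pH_acid must be below pH_external")


DEFAULT_CONSTANTS = Constants()


@dataclass
class CalibrationMeasurement:
    """Per-punctum calibration amplitudes with responder gating flags."""

    punctum_id: str
    genotype: str
    gamma: float
    epsilon: float
    kcl_responder: bool = True
    nh4_responder: bool = True
    mes_responder: bool = True

    @property
    def valid(self) -> bool:
        return (
            np.isfinite(self.gamma)
            and np.isfinite(self.epsilon)
            and self.kcl_responder
            and self.nh4_responder
            and self.mes_responder
        )


@dataclass
class PHSolution:
    """Inferred lumenal pH and surface fraction for one punctum."""

    punctum_id: str
    pH: float
    SF: float
    converged: bool
    excluded: bool
    reason: Literal["none", "below_dynamic_range", "no_intersection"] = "none"

    @property
    def usable(self) -> bool:
        return self.converged and not self.excluded


@dataclass
class DeltaAdjustment:
    """Genotype-level exocytosis correction: ratio = delta_ref / delta_mut."""

    genotype: str
    delta_ref: float
    delta_mut: float

    @property
    def ratio(self) -> float:
        return self.delta_ref / self.delta_mut


def _alkalinization_gain(pH: float, c: Constants) -> float:
    """A(pH): fractional signal gain when lumenal pH rises to external pH."""
    pk, pe = c.pK, c.pH_external
    return (10 ** (pk - pH) - 10 ** (pk - pe)) / (1 + 10 ** (pk - pe))


def _acid_quench(pH: float, c: Constants) -> float:
    """C(pH): signal ratio when the probe environment drops to the MES pH."""
    return (1 + 10 ** (c.pK - pH)) / (1 + 10 ** (c.pK - c.pH_acid))


def measure_gamma(
    trace: TimeSeriesTrace,
    nh4_window: WindowSpec | None = None,
    filter_width: float = 5.0,
) -> float:
    """NH4Cl fractional increase: max smoothed dF/F during application (20-60 s)."""
    if nh4_window is None:
        nh4_window = WindowSpec(20.0, 60.0)
    smoothed = moving_average(trace, filter_width)
    return float(smoothed.window_values(nh4_window, "dff").max())


def measure_epsilon(
    trace: TimeSeriesTrace,
    mes_window: WindowSpec | None = None,
    filter_width: float = 5.0,
) -> float:
    """MES fractional decrease magnitude: -(min smoothed dF/F) during 20-80 s."""
    if mes_window is None:
        mes_window = WindowSpec(20.0, 80.0)
    smoothed = moving_average(trace, filter_width)
    return -float(smoothed.window_values(mes_window, "dff").min())


def sf_from_gamma(pH: float, gamma: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Surface fraction implied by the NH4Cl response at a candidate pH."""
    A = _alkalinization_gain(pH, constants)
    if A == 0:
        raise ValueError("pH equals external pH: NH4Cl response carries no information")
    return (A - gamma) / (A * (gamma + 1))


def sf_from_epsilon(pH: float, epsilon: float, constants: Constants = DEFAULT_CONSTANTS) -> float:
    """Surface fraction implied by the MES response at a candidate pH."""
    A = _alkalinization_gain(pH, constants)
    C = _acid_quench(pH, constants)
    denom = 1 - C + (1 - epsilon) * A
    if denom == 0:
        raise ZeroDivisionError("singular denominator in MES surface-fraction relation")
    return epsilon / denom


def forward_calibration(
    pH: float, SF: float, constants: Constants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Predicted (gamma, epsilon) for a punctum with known pH and SF.

    Exact algebraic inverse of :func:`sf_from_gamma` / :func:`sf_from_epsilon`;
    used to generate synthetic calibrations and for round-trip testing.
    SF = 1 is degenerate (all probe at the surface: gamma = 0 at any pH).
    """
    if not 0 <= SF < 1:
        raise ValueError(f"SF must be in [0, 1), got {SF}")
    if pH > constants.pH_external:
        raise ValueError(f"pH {pH} above external pH {constants.pH_external}")
    A = _alkalinization_gain(pH, constants)
    C = _acid_quench(pH, constants)
    gamma = A * (1 - SF) / (1 + A * SF)
    epsilon = SF * (1 - C + A) / (1 + SF * A)
    return gamma, epsilon


def solve_ph_sf(
    gamma: float,
    epsilon: float,
    constants: Constants = DEFAULT_CONSTANTS,
    tol: float = 1e-9,
    bracket: tuple[float, float] | None = None,
    punctum_id: str = "",
    grid_step: float = 1e-3,
) -> PHSolution:
    """Solve for lumenal pH and SF by intersecting the two calibration curves.

    The difference SF_gamma(pH) - SF_epsilon(pH) is scanned on a
    ``grid_step`` pH grid over ``bracket`` (default: pH_acid + 1e-6 to
    pH_external - 1e-6); each sign change is refined by Brent's method to
    |dpH| < 1e-7.  With several sign changes the root with the smallest
    residual is kept and a warning is issued.  Solutions below pH_floor
    (5.0) are flagged excluded (outside the probe's dynamic range);
    absence of any sign change yields converged=False.
    """
    if not (np.isfinite(gamma) and np.isfinite(epsilon)):
        raise ValueError("gamma and epsilon must be finite")
    if bracket is None:
        bracket = (constants.pH_acid + 1e-6, constants.pH_external - 1e-6)

    def diff(pH):
        # vectorized evaluation of SF_gamma(pH) - SF_epsilon(pH)
        A = _alkalinization_gain(pH, constants)
        C = _acid_quench(pH, constants)
        return (A - gamma) / (A * (gamma + 1)) - epsilon / (1 - C + (1 - epsilon) * A)

    grid = np.arange(bracket[0], bracket[1] + grid_step / 2, grid_step)
    grid[-1] = min(grid[-1], bracket[1])
    vals = diff(grid)
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]

    roots: list[float] = []
    for i in crossings:
        if vals[i] == 0:
            roots.append(float(grid[i]))
        else:
            roots.append(float(brentq(diff, grid[i], grid[i + 1], xtol=1e-7)))
    if vals[-1] == 0:
        roots.append(float(grid[-1]))

    if not roots:
        return PHSolution(punctum_id, float("nan"), float("nan"),
                          converged=False, excluded=False, reason="no_intersection")
    if len(roots) > 1:
        warnings.warn(
            f"punctum {punctum_id or '<anon>'}: {len(roots)} intersections; "
            "keeping the smallest-residual root",
            RuntimeWarning,
            stacklevel=2,
        )
        roots.sort(key=lambda p: abs(diff(p)))
    pH_star = roots[0]
    SF_star = sf_from_gamma(pH_star, gamma, constants)
    residual = abs(diff(pH_star))
    converged = residual < max(tol, 1e-6)
    if pH_star < constants.pH_floor:
        return PHSolution(punctum_id, pH_star, SF_star, converged,
                          excluded=True, reason="below_dynamic_range")
    return PHSolution(punctum_id, pH_star, SF_star, converged,
                      excluded=False, reason="none")


def delta_factor(
    pH_a: float, SF: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Fractional signal increase for an exocytosis event from pH_a to 7.2.

    delta = (f(7.2) - f(pH_a)) / (f(pH_a) + SF / ((1-SF) (1+10^(pK-7.2))))
    where f is the probe's deprotonated fraction.  delta vanishes at
    pH_a = 7.2 and grows as the resting vesicle gets more acidic.
    """
    if not 0 <= SF < 1:
        raise ValueError(f"SF must be in [0, 1), got {SF}")
    if pH_a > constants.pH_external:
        raise ValueError(f"pH_a {pH_a} above external pH")
    pk, pe = constants.pK, constants.pH_external
    f_ext = 1 / (1 + 10 ** (pk - pe))
    f_a = 1 / (1 + 10 ** (pk - pH_a))
    return (f_ext - f_a) / (f_a + SF / ((1 - SF) * (1 + 10 ** (pk - pe))))


def delta_ratio(
    pH_ref: float,
    pH_mut: float,
    SF_mut: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Correction factor delta_ref/delta_mut for depolarization responses.

    Both delta factors are evaluated at the mutant genotype's surface
    fraction; only the resting pH differs (reference pH in the numerator,
    mutant pH in the denominator).  Multiplying a mutant's evoked signal
    by this ratio expresses it as if its vesicles rested at the reference
    pH with everything else unchanged.
    """
    d_mut = delta_factor(pH_mut, SF_mut, constants)
    if d_mut == 0:
        raise ZeroDivisionError("mutant delta factor is zero (pH_mut at external pH)")
    return delta_factor(pH_ref, SF_mut, constants) / d_mut


def adjust_exocytosis_signal(signal: float, ratio: float) -> float:
    """Rescale a per-punctum evoked signal by a delta-ratio correction."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return signal * ratio


def summarize_genotype(
    solutions: Iterable[PHSolution],
) -> tuple[float, float, int, float, float]:
    """Mean pH, mean SF, n, and SDs over usable (converged, non-excluded) solutions.

    Returns ``(mean_pH, mean_SF, n, sd_pH, sd_SF)``; SDs are NaN at n = 1.
    """
    usable = [s for s in solutions if s.usable]
    if not usable:
        raise ValueError("no usable pH solutions to summarize")
    ph = np.array([s.pH for s in usable])
    sf = np.array([s.SF for s in usable])
    n = len(usable)
    sd_ph = float(ph.std(ddof=1)) if n > 1 else float("nan")
    sd_sf = float(sf.std(ddof=1)) if n > 1 else float("nan")
    return float(ph.mean()), float(sf.mean()), n, sd_ph, sd_sf
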