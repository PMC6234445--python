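"""Respiratory flow parameters for age-specific airway modelling.

Converts breathing patterns (tidal volume, respiratory rate, I:E ratio)
into minute ventilation, phase flow rates, per-branch flow rates under a
symmetric dichotomous (Weibel-type) split, inlet velocities, and the
dimensionless numbers (Reynolds, Womersley) that justify the steady
laminar treatment of the flow.

Units follow clinical convention at the interface (mL, breaths/min,
L/min) and SI internally (m, s, kg): conversion happens only in
:func:`branch_flow_rate` and downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "FluidProperties",
    "BreathingPattern",
    "PhaseFlow",
    "AIR",
    "breathing_pattern",
    "interpolate_pattern",
    "minute_ventilation",
    "phase_flow_rates",
    "branch_flow_rate",
    "mean_inlet_velocity",
    "reynolds_number",
    "womersley_number",
    "phase_flow",
]

Phase = Literal["inspiration", "expiration"]


@dataclass(frozen=True)
class FluidProperties:
    """Air at sea level (U.S. Standard Atmosphere)."""

    density: float = 1.225  # kg/m^3
    dynamic_viscosity: float = 1.7894e-5  # kg/(m s)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


#: Default working fluid for every computation in the package.
AIR = FluidProperties()


@dataclass(frozen=True)
class BreathingPattern:
    """Normal-breathing parameters of one subject.

    ``ie_ratio`` is the inspiration-to-expiration duration ratio,
    normalized on construction so the inspiratory part is 1.
    """

    tidal_volume_ml: float
    respiratory_rate: float  # breaths/min
    ie_ratio: tuple[float, float] = (1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        if self.tidal_volume_ml < 0:
            raise ValueError("tidal volume must be non-negative")
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory rate must be positive")
        t_i, t_e = self.ie_ratio
        if t_i <= 0 or t_e <= 0:
            raise ValueError("I:E durations must be positive")
        if t_i != 1.0:
            object.__setattr__(self, "ie_ratio", (1.0, t_e / t_i))


@dataclass(frozen=True)
class PhaseFlow:
    """Steady plug flow of one breathing phase, split down to one branch."""

    phase: Phase
    total_flow_rate_lpm: float  # whole-lung flow, L/min
    model_inlet_generation: int
    branch_flow_rate_m3s: float  # at model_inlet_generation, m^3/s


# Normal-breathing parameter anchors: 6-month-old infant, 5-year-old child,
# 25-year-old adult (tidal volume mL, rate breaths/min, I:E).
_PATTERNS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "infant": (39.0, 36.0, (1.0, 1.5)),
    "child": (181.0, 20.0, (1.0, 1.7)),
    "adult": (500.0, 14.0, (1.0, 1.7)),
}

_ANCHOR_AGES: list[tuple[float, str]] = [(0.5, "infant"), (5.0, "child"), (25.0, "adult")]


def breathing_pattern(name: str) -> BreathingPattern:
    """Embedded normal-breathing parameters for a named age group."""
    try:
        tv, rr, ie = _PATTERNS[name]
    except KeyError:
        raise ValueError(
            f"unknown age group {name!r}; expected one of {sorted(_PATTERNS)}"
        ) from None
    return BreathingPattern(tv, rr, ie, name=name)


def interpolate_pattern(age_years: float) -> BreathingPattern:
    """Piecewise-linear breathing pattern between the anchor ages 0.5, 5, 25.

    At an anchor age the anchor pattern is returned exactly.
    """
    lo, hi = _ANCHOR_AGES[0][0], _ANCHOR_AGES[-1][0]
    if not lo <= age_years <= hi:
        raise ValueError(f"age {age_years} outside supported range [{lo}, {hi}] years")
    for (a0, n0), (a1, n1) in zip(_ANCHOR_AGES, _ANCHOR_AGES[1:]):
        if age_years <= a1:
            w = (age_years - a0) / (a1 - a0)
            tv0, rr0, ie0 = _PATTERNS[n0]
            tv1, rr1, ie1 = _PATTERNS[n1]
            return BreathingPattern(
                tv0 + w * (tv1 - tv0),
                rr0 + w * (rr1 - rr0),
                (1.0, ie0[1] + w * (ie1[1] - ie0[1])),
                name=f"age_{age_years:g}y",
            )
    raise AssertionError("unreachable")


def minute_ventilation(pattern: BreathingPattern) -> float:
    """Minute ventilation in mL/min: tidal volume times respiratory rate."""
    return pattern.tidal_volume_ml * pattern.respiratory_rate


def phase_flow_rates(pattern: BreathingPattern) -> tuple[float, float]:
    """Steady (Q_insp, Q_exp) in L/min for square-wave breathing.

    Each phase moves the full tidal volume in its fraction of the cycle, so
    Q_insp = MV (t_i+t_e)/t_i and Q_exp = MV (t_i+t_e)/t_e with MV the
    minute ventilation.
    """
    mv = minute_ventilation(pattern)  # mL/min
    t_i, t_e = pattern.ie_ratio
    total = t_i + t_e
    return mv * total / t_i / 1000.0, mv * total / t_e / 1000.0


def branch_flow_rate(q_total_lpm: float, generation: int) -> float:
    """Flow in one branch of generation ``g`` (m^3/s), symmetric Weibel split.

    The whole-lung flow halves at every bifurcation, so a single branch of
    generation g carries Q_total / 2**g.
    """
    if generation < 0:
        raise ValueError("generation must be non-negative")
    if q_total_lpm < 0:
        raise ValueError("flow rate must be non-negative")
    return q_total_lpm / 2**generation * 1e-3 / 60.0


def mean_inlet_velocity(q_branch_m3s: float, diameter_m: float) -> float:
    """Cross-section mean speed for a circular branch, Q / (pi D^2 / 4)."""
    if diameter_m <= 0:
        raise ValueError("diameter must be positive")
    return q_branch_m3s / (math.pi * diameter_m**2 / 4.0)


def reynolds_number(speed: float, diameter_m: float, fluid: FluidProperties = AIR) -> float:
    """Re = rho U D / mu."""
    return fluid.density * speed * diameter_m / fluid.dynamic_viscosity


def womersley_number(
    diameter_m: float, respiratory_rate: float, fluid: FluidProperties = AIR
) -> float:
    """Womersley number (D/2) sqrt(omega rho / mu), omega = 2 pi f.

    The characteristic length is the airway *radius*; the breathing
    frequency f is the respiratory rate converted to Hz.
    """
    omega = 2.0 * math.pi * respiratory_rate / 60.0
    return (diameter_m / 2.0) * math.sqrt(omega * fluid.density / fluid.dynamic_viscosity)


def phase_flow(
    pattern: BreathingPattern, phase: Phase, generation: int = 6
) -> PhaseFlow:
    """Branch flow of one phase at the model inlet generation."""
    q_insp, q_exp = phase_flow_rates(pattern)
    if phase == "inspiration":
        q = q_insp
    elif phase == "expiration":
        q = q_exp
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return PhaseFlow(phase, q, generation, branch_flow_rate(q, generation))
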