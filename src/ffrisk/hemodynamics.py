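"""Fractional flow reserve and a reduced-order stenosis pressure-drop model.

FFR is the ratio of maximal flow through a stenosed coronary artery to the
theoretical maximal flow through the same artery without stenosis.  With a
shared microvascular resistance R the flows are

    Q_N = (p_a - p_v) / R        (no stenosis)
    Q_S = (p_d - p_v) / R        (stenosis)

so FFR = Q_S / Q_N = (p_d - p_v) / (p_a - p_v) ≈ p_d / p_a, where p_a, p_d
and p_v are the mean aortic, distal and venous pressures.  R cancels and is
carried only symbolically.  A healthy artery has FFR = 1, and values at or
below 0.75 are the accepted criterion for stenting.

The distal pressure itself comes from a reduced-order model: the *excess*
Poiseuille drop of the stenotic segment relative to the same segment at its
reference radius,

    ΔP_excess = (8 μ L Q / π) (1 / r_s^4 - 1 / r_0^4),   r_s = r_0 (1 - f),

with f the fractional *diameter* reduction (the clinical percent-stenosis
convention).  This is a deliberate fidelity reduction from a full 3-D
Navier–Stokes simulation: it preserves the monotone stenosis → FFR mapping
that downstream classification consumes, with no mesh machinery.

Unit regime: pressures mmHg, flows mL/s, geometry m, viscosity Pa·s;
conversions are centralized in the constants below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "MMHG_TO_PA",
    "BLOOD_VISCOSITY",
    "BLOOD_DENSITY",
    "STENT_FFR_THRESHOLD",
    "HemodynamicState",
    "VesselSpec",
    "FfrValue",
    "flow_normal",
    "flow_stenosed",
    "ffr",
    "needs_stent",
    "excess_pressure_drop",
    "distal_pressure_reduced_order",
    "ffr_from_vessel",
    "stenosis_for_ffr",
]

MMHG_TO_PA = 133.322          # 1 mmHg in Pa
ML_S_TO_M3_S = 1e-6           # 1 mL/s in m^3/s
BLOOD_VISCOSITY = 0.00365     # Pa·s, blood as an incompressible Newtonian fluid
BLOOD_DENSITY = 1050.0        # kg/m^3
STENT_FFR_THRESHOLD = 0.75    # clinical criterion: stent iff FFR <= 0.75


@dataclass(frozen=True)
class HemodynamicState:
    """Pressures (mmHg), resistance (mmHg·s/mL) and flows (mL/s) for one
    FFR computation."""

    p_a: float
    p_d: float
    p_v: float
    R: float

    def __post_init__(self) -> None:
        if not self.p_v <= self.p_d <= self.p_a:
            raise ValueError("need p_v <= p_d <= p_a")
        if self.R <= 0:
            raise ValueError("resistance must be positive")

    @property
    def Q_N(self) -> float:
        return flow_normal(self.p_a, self.p_v, self.R)

    @property
    def Q_S(self) -> float:
        return flow_stenosed(self.p_d, self.p_v, self.R)


@dataclass(frozen=True)
class VesselSpec:
    """Geometry and boundary conditions of one stenosed vessel segment.

    ``stenosis_fraction`` is the fractional diameter reduction in [0, 1).
    Defaults: blood viscosity 0.00365 Pa·s, density 1050 kg/m³, inlet
    pressure 100 mmHg; 3 mL/s is the standard adenosine-induced hyperemic
    flow (1 mL/s the resting condition).
    """

    reference_radius: float          # m
    stenosis_fraction: float         # dimensionless, [0, 1)
    stenosis_length: float           # m
    flow_rate: float = 3.0           # mL/s
    dynamic_viscosity: float = BLOOD_VISCOSITY   # Pa·s
    density: float = BLOOD_DENSITY   # kg/m^3 (carried for completeness)
    inlet_pressure: float = 100.0    # mmHg
    venous_pressure: float = 0.0     # mmHg, clamp floor for p_d

    def __post_init__(self) -> None:
        if self.stenosis_fraction >= 1.0:
            raise ValueError("stenosis_fraction must be < 1 (total occlusion excluded)")
        if self.stenosis_fraction < 0.0:
            raise ValueError("stenosis_fraction must be >= 0")
        for name in ("reference_radius", "stenosis_length", "flow_rate",
                     "dynamic_viscosity", "density", "inlet_pressure"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class FfrValue(NamedTuple):
    """Exact pressure-ratio FFR and its venous-pressure-free approximation."""

    exact: float
    approximate: float


def flow_normal(p_a: float, p_v: float, R: float) -> float:
    """Flow through an artery without stenosis: (p_a - p_v) / R."""
    if R <= 0:
        raise ValueError("resistance must be positive")
    return (p_a - p_v) / R


def flow_stenosed(p_d: float, p_v: float, R: float) -> float:
    """Flow through an artery with stenosis: (p_d - p_v) / R."""
    if R <= 0:
        raise ValueError("resistance must be positive")
    return (p_d - p_v) / R


def ffr(p_d: float, p_a: float, p_v: float = 0.0) -> FfrValue:
    """FFR from mean pressures.

    exact = (p_d - p_v)/(p_a - p_v); approximate = p_d/p_a.  The two
    coincide when p_v = 0, and both equal 1 for a healthy artery
    (p_d = p_a).
    """
    if p_a <= p_v:
        raise ValueError("need p_a > p_v")
    if not p_v <= p_d <= p_a:
        raise ValueError("need p_v <= p_d <= p_a")
    return FfrValue((p_d - p_v) / (p_a - p_v), p_d / p_a)


def needs_stent(ffr_value: float) -> bool:
    """Clinical stenting criterion: FFR at or below 0.75."""
    if not 0.0 <= ffr_value <= 1.0:
        raise ValueError(f"FFR {ffr_value} outside [0, 1]")
    return ffr_value <= STENT_FFR_THRESHOLD


def excess_pressure_drop(vessel: VesselSpec) -> float:
    """Excess Poiseuille drop of the stenotic segment, in Pa.

    (8 μ L Q / π)(1/r_s⁴ − 1/r₀⁴) with r_s = r₀(1 − f); exactly zero at
    f = 0 by construction.
    """
    r0 = vessel.reference_radius
    rs = r0 * (1.0 - vessel.stenosis_fraction)
    q = vessel.flow_rate * ML_S_TO_M3_S
    k = 8.0 * vessel.dynamic_viscosity * vessel.stenosis_length * q / math.pi
    return k * (1.0 / rs**4 - 1.0 / r0**4)


def distal_pressure_reduced_order(vessel: VesselSpec) -> float:
    """Mean distal pressure (mmHg) behind the stenosis.

    Inlet pressure minus the excess Poiseuille drop, clamped at the venous
    pressure so extreme stenoses degrade gracefully instead of going
    negative.
    """
    drop_mmhg = excess_pressure_drop(vessel) / MMHG_TO_PA
    p_d = vessel.inlet_pressure - drop_mmhg
    return max(p_d, vessel.venous_pressure)


def ffr_from_vessel(vessel: VesselSpec) -> FfrValue:
    """FFR of a vessel under the reduced-order model."""
    p_d = distal_pressure_reduced_order(vessel)
    return ffr(p_d, vessel.inlet_pressure, vessel.venous_pressure)


def stenosis_for_ffr(target_ffr: float, vessel: VesselSpec) -> float:
    """Invert the reduced-order model: the stenosis fraction whose exact FFR
    equals ``target_ffr`` for this vessel's geometry and flow.

    Closed form: the required excess drop fixes 1/r_s⁴, hence r_s, hence
    f = 1 − r_s/r₀.  Raises if the target is unreachable (> 1 or ≤ 0).
    """
    if not 0.0 < target_ffr <= 1.0:
        raise ValueError("target FFR must be in (0, 1]")
    drop_mmhg = (vessel.inlet_pressure - vessel.venous_pressure) * (1.0 - target_ffr)
    drop_pa = drop_mmhg * MMHG_TO_PA
    r0 = vessel.reference_radius
    q = vessel.flow_rate * ML_S_TO_M3_S
    k = 8.0 * vessel.dynamic_viscosity * vessel.stenosis_length * q / math.pi
    inv_rs4 = drop_pa / k + 1.0 / r0**4
    rs = inv_rs4 ** -0.25
    return 1.0 - rs / r0
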