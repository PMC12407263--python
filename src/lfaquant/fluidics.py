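"""Capillary-fluidics design equations for the passive volume-control chip.

Design calculator for a pad-integrated microfluidic casing that meters a
fixed blood volume onto the strip without pumps: the Laplace pressure at
the liquid/air meniscus drives the flow, Hagen-Poiseuille gives the
resulting rate in the capillary, and the Washburn relation gives the
filling dynamics of a channel under constant capillary pressure.  Blood is
treated as Newtonian with a configurable effective viscosity (an override
hook is the ``mu`` field itself); all quantities are SI internally with
microlitre/millimetre helpers for bench units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError

# reservoir volumes of the two prototypes, for convenience in design reports
PROTOTYPE1_VOLUME_UL = 150.0   # direct-wicking casing
PROTOTYPE2_INLET_UL = 60.0     # capillary-driven casing inlet reservoir
PROTOTYPE2_CHANNEL_UL = 25.0   # its microfluidic channel volume


@dataclass(frozen=True)
class FluidSpec:
    """gamma: surface tension (N/m); theta: contact angle (rad);
    mu: dynamic viscosity (Pa s)."""

    gamma: float
    theta: float
    mu: float

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.mu <= 0:
            raise ConfigError("surface tension and viscosity must be positive")
        if not (0.0 <= self.theta <= math.pi):
            raise ConfigError("contact angle must be within [0, pi]")


#: Whole blood at body temperature: gamma ~ 55 mN/m, wetting on treated
#: PDMS/paper (theta ~ 60 deg), effective viscosity ~ 4 mPa s.
BLOOD = FluidSpec(gamma=0.055, theta=math.radians(60.0), mu=4e-3)
WATER = FluidSpec(gamma=0.072, theta=0.0, mu=1e-3)


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular (w x h) or cylindrical (radius r) channel of length L, SI."""

    shape: str                    # "rectangular" | "cylindrical"
    L: float
    w: float | None = None
    h: float | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "rectangular":
            if not (self.w and self.h) or self.w <= 0 or self.h <= 0:
                raise ConfigError("rectangular channel needs w > 0 and h > 0")
        elif self.shape == "cylindrical":
            if not self.r or self.r <= 0:
                raise ConfigError("cylindrical channel needs r > 0")
        else:
            raise ConfigError(f"unknown channel shape {self.shape!r}")
        if self.L <= 0:
            raise ConfigError("channel length must be positive")

    @property
    def volume(self) -> float:
        if self.shape == "rectangular":
            return self.w * self.h * self.L
        return math.pi * self.r**2 * self.L


def laplace_pressure(fluid: FluidSpec, geom: ChannelGeometry) -> float:
    """Capillary driving pressure of a rectangular channel meniscus:
    dP = 2 gamma cos(theta) (1/w + 1/h), in Pa."""
    if geom.shape != "rectangular":
        raise ConfigError("Laplace pressure formula applies to rectangular channels")
    return 2.0 * fluid.gamma * math.cos(fluid.theta) * (1.0 / geom.w + 1.0 / geom.h)


def poiseuille_flow(fluid: FluidSpec, geom: ChannelGeometry, delta_p: float) -> float:
    """Laminar volumetric flow rate in a cylindrical capillary:
    Q = pi r^4 dP / (8 mu L), in m^3/s."""
    if geom.shape != "cylindrical":
        raise ConfigError("Hagen-Poiseuille formula applies to cylindrical channels")
    if delta_p < 0:
        raise ValueError("negative pressure difference: backflow not modelled")
    return math.pi * geom.r**4 * delta_p / (8.0 * fluid.mu * geom.L)


def washburn_fill(fluid: FluidSpec, diameter: float, t: float) -> float:
    """Filled length after time t under constant capillary pressure:
    L = sqrt(gamma D cos(theta) t / (4 mu)), in m."""
    if t < 0:
        raise ValueError("time must be non-negative")
    cos_t = math.cos(fluid.theta)
    if cos_t <= 0 and t > 0:
        raise ValueError("non-wetting fluid (theta >= 90 deg): no capillary fill")
    return math.sqrt(fluid.gamma * diameter * cos_t * t / (4.0 * fluid.mu))


def washburn_time(fluid: FluidSpec, diameter: float, L: float) -> float:
    """Exact inverse of washburn_fill: time to fill length L."""
    if L < 0:
        raise ValueError("length must be non-negative")
    cos_t = math.cos(fluid.theta)
    if cos_t <= 0 and L > 0:
        raise ValueError("non-wetting fluid (theta >= 90 deg): no capillary fill")
    if L == 0:
        return 0.0
    return 4.0 * fluid.mu * L**2 / (fluid.gamma * diameter * cos_t)


def reservoir_fill_time(reservoir_volume: float, q: float) -> float:
    """Time to pass a reservoir volume (m^3) at flow rate q (m^3/s)."""
    if q <= 0:
        raise ValueError("flow rate must be positive")
    return reservoir_volume / q


# ---- unit helpers (exact round trips) ----

def ul_to_m3(v_ul: float) -> float:
    return v_ul * 1e-9


def m3_to_ul(v_m3: float) -> float:
    return v_m3 * 1e9


def mm_to_m(x_mm: float) -> float:
    return x_mm * 1e-3


def m_to_mm(x_m: float) -> float:
    return x_m * 1e3


def design_report(
    fluid: FluidSpec,
    driving: ChannelGeometry,
    capillary: ChannelGeometry,
    target_volume_ul: float = PROTOTYPE2_INLET_UL,
) -> dict:
    """Chained design check: meniscus pressure in the driving channel,
    flow through the capillary, and the reservoir fill time, in bench units."""
    dp = laplace_pressure(fluid, driving)
    q = poiseuille_flow(fluid, capillary, dp)
    t = reservoir_fill_time(ul_to_m3(target_volume_ul), q)
    return {
        "laplace_pressure_pa": dp,
        "flow_rate_ul_per_s": m3_to_ul(q),
        "fill_time_s": t,
        "target_volume_ul": target_volume_ul,
        "fluid": {"gamma_n_per_m": fluid.gamma, "theta_deg": math.degrees(fluid.theta),
                  "mu_pa_s": fluid.mu},
    }
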