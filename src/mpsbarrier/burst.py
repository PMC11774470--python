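"""Quasi-static capillary burst-valve analysis of a single fenestra.

A fenestra (pore) in the barrier behaves as a capillary burst valve: an
advancing water meniscus pins wherever the walls diverge, and the valve
"bursts" when the applied pressure exceeds the largest pinned Laplace
pressure along the crossing path.  The advancing contact angle on a wall
diverging at angle β is pinned at θ* = min(θ_c + β, 180°); the local
Laplace pressure across a gap of width w(s) and height h is

    Δp(s) = −2γ [ cos θ*(s)/w(s) + cos θ_v/h ],

with θ_v = θ_c inside the fenestra, and θ_v = θ*(exit) at the exit
expansion where the meniscus pins in both transverse directions.  Burst
pressures are reported both raw and as the non-dimensional pressure
p* = Δp · D_h / γ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import FenestraPath

__all__ = ["FluidPair", "BurstResult", "pstar", "quasi_static_burst", "WATER_AIR"]


@dataclass(frozen=True)
class FluidPair:
    """Interfacial and bulk properties of the liquid/gas pair."""

    surface_tension: float = 0.072  # N/m
    contact_angle_deg: float = 66.0  # advancing angle on the wall material
    water_viscosity: float = 1.0e-3  # Pa·s
    air_viscosity: float = 1.8e-5  # Pa·s
    water_density: float = 998.0  # kg/m³
    air_density: float = 1.2  # kg/m³

    def __post_init__(self) -> None:
        if self.surface_tension <= 0:
            raise ValueError("surface tension must be positive")
        if not 0.0 < self.contact_angle_deg < 180.0:
            raise ValueError("contact angle must be in (0°, 180°)")
        for name in ("water_viscosity", "air_viscosity", "water_density", "air_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def contact_angle_rad(self) -> float:
        return math.radians(self.contact_angle_deg)


#: Water against air on plasma-treated PDMS (advancing angle 66°).
WATER_AIR = FluidPair()


@dataclass
class BurstResult:
    """Burst pressure of a fenestra with its non-dimensional form."""

    burst_pressure: float  # Pa
    p_star: float
    burst_position: float  # s [m] along the path; path end ⇒ exit plane
    method: str  # "quasi_static" | "simulated"


def pstar(dp: float, dh: float, gamma: float) -> float:
    """Non-dimensional pressure p* = Δp·D_h/γ."""
    if dh <= 0 or gamma <= 0:
        raise ValueError("hydraulic diameter and surface tension must be positive")
    return dp * dh / gamma


def _pinned_cos(theta_c_deg: float, beta_deg: np.ndarray | float) -> np.ndarray:
    """cos of the pinned advancing angle θ* = min(θ_c + max(β,0), 180°)."""
    theta = np.minimum(theta_c_deg + np.maximum(beta_deg, 0.0), 180.0)
    return np.cos(np.radians(theta))


def quasi_static_burst(
    path: FenestraPath,
    fluid: FluidPair = WATER_AIR,
    include_exit: bool = True,
) -> BurstResult:
    """Burst pressure of a fenestra from the pinned-meniscus Laplace model.

    Scans the sampled path (and, if ``include_exit``, a virtual exit plane
    with β = 90° where the meniscus pins in both transverse directions)
    and returns the maximum pinned Laplace pressure and its position.  A
    uniform straight channel with θ_c < 90° and no exit treatment yields a
    non-positive burst pressure (spontaneous wicking).
    """
    if path.s.size < 200:
        raise ValueError(
            f"path has {path.s.size} samples; the pinning scan requires >= 200"
        )
    gamma = fluid.surface_tension
    theta_c = fluid.contact_angle_deg
    h = path.height

    cos_star = _pinned_cos(theta_c, path.divergence_deg)
    cos_v = math.cos(fluid.contact_angle_rad)  # top/bottom walls inside the fenestra
    dp = -2.0 * gamma * (cos_star / path.width + cos_v / h)

    candidates = list(zip(dp, path.s))
    if include_exit:
        cos_exit = float(_pinned_cos(theta_c, 90.0))
        w_exit = float(path.width[-1])
        dp_exit = -2.0 * gamma * (cos_exit / w_exit + cos_exit / h)
        candidates.append((dp_exit, float(path.s[-1])))

    values = np.array([c[0] for c in candidates])
    k = int(np.argmax(values))
    dp_b = float(values[k])
    return BurstResult(
        burst_pressure=dp_b,
        p_star=pstar(dp_b, path.hydraulic_diameter, gamma),
        burst_position=float(candidates[k][1]),
        method="quasi_static",
    )
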