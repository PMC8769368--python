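"""First-order propagation of measurement uncertainty to derived kinematics.

Relative uncertainties of the primary measurements — length (pixel scale /
grid precision), time (one frame interval over the phase duration) and mass
(balance resolution) — are combined in quadrature with the exponents of
each derived quantity:

    velocity      v = L / t              -> sqrt( (uL/L)^2 + (ut/t)^2 )
    acceleration  a = L / t^2            -> sqrt( (uL/L)^2 + (2 ut/t)^2 )
    energy        E = 1/2 m v^2          -> sqrt( (um/m)^2 + (2 uv/v)^2 )
    power         P = m L^2 / t^3        -> sqrt( (um/m)^2 + (2 uL/L)^2 + (3 ut/t)^2 )
    power density O = P / (m c)          -> power term plus (uc/c)^2

These are the standard independent first-order formulas; correlations
between inputs are neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["UncertaintyBudget", "propagate", "budget_for_jump"]

_QUANTITIES = ("velocity", "acceleration", "energy", "power", "power_density")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Relative (dimensionless) uncertainties of the primary inputs."""

    rel_length: float = 0.0
    rel_time: float = 0.0
    rel_mass: float = 0.0
    rel_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rel_length", "rel_time", "rel_mass", "rel_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def propagate(budget: UncertaintyBudget, quantity: str) -> float:
    """Relative uncertainty of a derived quantity under first-order quadrature."""
    L, t, m, c = (budget.rel_length, budget.rel_time,
                  budget.rel_mass, budget.rel_fraction)
    if quantity == "velocity":
        return math.hypot(L, t)
    if quantity == "acceleration":
        return math.hypot(L, 2 * t)
    if quantity == "energy":
        return math.hypot(m, 2 * math.hypot(L, t))
    if quantity == "power":
        return math.sqrt(m ** 2 + (2 * L) ** 2 + (3 * t) ** 2)
    if quantity == "power_density":
        return math.sqrt(m ** 2 + (2 * L) ** 2 + (3 * t) ** 2 + c ** 2)
    raise ValueError(f"unknown quantity {quantity!r}; expected one of {_QUANTITIES}")


def budget_for_jump(displacement: float, duration: float, frame_rate: float,
                    mass: float, length_uncertainty: float,
                    mass_uncertainty: float = 1e-7,
                    fraction_uncertainty: float = 0.0,
                    fraction: float = 1.0) -> UncertaintyBudget:
    """Budget for one jump from its pooled latch+launch window measurements.

    ``length_uncertainty`` is the absolute uncertainty of the displacement
    L (typically one pixel in metres, dominated by the centroid and grid
    calibration); the time uncertainty is one frame interval over the
    window duration; the mass uncertainty defaults to a 0.1 mg balance
    resolution.
    """
    if displacement <= 0 or duration <= 0 or frame_rate <= 0 or mass <= 0:
        raise ValueError("displacement, duration, frame_rate and mass must be positive")
    return UncertaintyBudget(
        rel_length=length_uncertainty / displacement,
        rel_time=(1.0 / frame_rate) / duration,
        rel_mass=mass_uncertainty / mass,
        rel_fraction=fraction_uncertainty / fraction,
    )
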