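"""Jump energetics: energy, power, muscle power density and cost of transport.

Core quantities, per jump:

- kinetic energy            E = 1/2 m v^2
- jump power                P = m L^2 / t^3, with L the centre-of-mass path
  displacement and t the duration of the pooled latch-decoupling + launch
  window (average power delivered over that window)
- muscle power density      O(c) = P / (m c), watts per kilogram of muscle,
  where c is the assumed fraction of body mass that is jump-powering muscle
- cost of transport         COT_jump = (1/eta) E / (m d), with muscle
  efficiency eta (default 10%) and d the horizontal jump distance
- crawling reference        COT_crawl = 10.8 m^-0.32 (allometric regression
  for legged arthropods, m in kg)

A jump whose power density exceeds the highest average power density
measured from any muscle (~400 W/kg, vertebrate flight muscle) cannot be
driven by direct muscle contraction and implies latch-mediated spring
actuation (LaMSA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Morphometrics",
    "EnergeticsResult",
    "ScenarioSweep",
    "DEFAULT_FRACTIONS",
    "POWER_DENSITY_CEILING",
    "kinetic_energy",
    "jump_power",
    "power_density",
    "muscle_fraction",
    "scenario_sweep",
    "critical_fraction",
    "cot_jump",
    "cot_crawl",
]

#: Muscle-mass-fraction scenarios swept by default: 100%, 75%, 50%, the
#: critical fraction 32.31%, 2x the microCT estimate (shrinkage allowance),
#: the microCT estimate itself (9.78%) and half of it.
DEFAULT_FRACTIONS = (1.0, 0.75, 0.50, 0.3231, 0.1960, 0.0978, 0.0489)

#: Highest known maximum average muscle power density, W per kg muscle.
POWER_DENSITY_CEILING = 400.0


def _check_mass(m: float) -> None:
    if m <= 0:
        raise ValueError(f"mass must be positive, got {m}")
    if m > 1.0 or m < 1e-9:
        warnings.warn(
            f"mass {m} kg is outside the plausible range for insect larvae "
            "(1e-9 to 1 kg); check units", stacklevel=3,
        )


@dataclass(frozen=True)
class Morphometrics:
    """Body measurements feeding the energetics.

    Defaults are the study-cohort averages: 1.3 mg body mass, 5.55 mm body
    length, and 0.12 mm^3 total muscle volume from microCT at an assumed
    muscle density of 1060 kg m^-3 (giving a 9.78% muscle mass fraction).
    """

    body_mass: float = 1.3e-6
    body_length: float = 5.55e-3
    muscle_volume: float = 1.2e-10
    muscle_density: float = 1060.0
    mass_uncertainty: float = 1e-7  # balance resolution, kg

    def __post_init__(self) -> None:
        _check_mass(self.body_mass)
        for name in ("body_length", "muscle_volume", "muscle_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def muscle_fraction(self) -> float:
        return muscle_fraction(self.muscle_volume, self.muscle_density, self.body_mass)


def kinetic_energy(mass: float, velocity: float) -> float:
    """E = 1/2 m v^2 (J)."""
    _check_mass(mass)
    if velocity < 0:
        raise ValueError(f"velocity must be non-negative, got {velocity}")
    return 0.5 * mass * velocity ** 2


def jump_power(mass: float, displacement: float, duration: float) -> float:
    """Average jump power P = m L^2 / t^3 (W) over the latch+launch window."""
    _check_mass(mass)
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if displacement < 0:
        raise ValueError(f"displacement must be non-negative, got {displacement}")
    return mass * displacement ** 2 / duration ** 3


def power_density(power: float, mass: float, fraction: float) -> float:
    """O = P / (m c): power per kilogram of assumed jump-powering muscle."""
    _check_mass(mass)
    if not 0 < fraction <= 1:
        raise ValueError(f"muscle fraction must be in (0, 1], got {fraction}")
    if power < 0:
        raise ValueError(f"power must be non-negative, got {power}")
    return power / (mass * fraction)


def muscle_fraction(volume: float, density: float, body_mass: float) -> float:
    """Muscle mass fraction c = V rho / m from a muscle volume measurement."""
    if volume <= 0 or density <= 0:
        raise ValueError("muscle volume and density must be positive")
    _check_mass(body_mass)
    frac = volume * density / body_mass
    if frac >= 1:
        raise ValueError(
            f"non-physical muscle fraction {frac:.3g} >= 1; check volume/mass units"
        )
    return frac


def critical_fraction(max_specific_power: float,
                      threshold: float = POWER_DENSITY_CEILING) -> float:
    """Smallest muscle fraction at which no jump exceeds the muscle ceiling.

    ``max_specific_power`` is the cohort maximum body-mass-specific power
    P/m (W per kg body). For any fraction c > c* = (P/m)_max / threshold,
    every jump's power density falls below the threshold.
    """
    if max_specific_power < 0 or threshold <= 0:
        raise ValueError("inputs must be positive")
    return max_specific_power / threshold


def cot_jump(energy: float, mass: float, distance: float,
             efficiency: float = 0.10) -> float:
    """Cost of transport of a jump, (1/efficiency) E / (m d), J kg^-1 m^-1."""
    _check_mass(mass)
    if distance <= 0:
        raise ValueError(f"jump distance must be positive, got {distance}")
    if not 0 < efficiency <= 1:
        raise ValueError(f"efficiency must be in (0, 1], got {efficiency}")
    if energy < 0:
        raise ValueError("energy must be non-negative")
    return energy / (efficiency * mass * distance)


def cot_crawl(mass: float, coefficient: float = 10.8, exponent: float = -0.32) -> float:
    """Crawling cost of transport from the arthropod allometry 10.8 m^-0.32."""
    _check_mass(mass)
    return coefficient * mass ** exponent


@dataclass(frozen=True)
class ScenarioSweep:
    """Power density of every jump under each muscle-fraction scenario.

    ``power_density`` is a (jump x fraction) DataFrame; ``exceeds`` flags
    entries above the threshold. Rows carry larva ids when provided.
    """

    power_density: pd.DataFrame
    exceeds: pd.DataFrame
    threshold: float
    larva_ids: np.ndarray | None = None

    def n_larvae_any_exceeds(self, fraction: float) -> int:
        """Number of larvae with at least one jump above threshold at ``fraction``."""
        return int(self._per_larva(fraction, "max").gt(self.threshold).sum())

    def n_larvae_mean_exceeds(self, fraction: float) -> int:
        """Number of larvae whose mean jump power density exceeds the threshold."""
        return int(self._per_larva(fraction, "mean").gt(self.threshold).sum())

    def n_jumps_exceeds(self, fraction: float) -> int:
        return int(self.exceeds[fraction].sum())

    def _per_larva(self, fraction: float, how: str) -> pd.Series:
        if self.larva_ids is None:
            raise ValueError("no larva ids attached to this sweep")
        col = self.power_density[fraction]
        return col.groupby(self.larva_ids).agg(how)


def scenario_sweep(powers, mass: float, fractions=DEFAULT_FRACTIONS,
                   threshold: float = POWER_DENSITY_CEILING,
                   larva_ids=None) -> ScenarioSweep:
    """Sweep muscle-fraction scenarios for a set of per-jump powers (W).

    Since O(c) = P/(m c), the products O(c)*c are identical across
    scenarios for one jump, and threshold flags are monotone: a jump
    exceeding the ceiling at c exceeds it at every smaller c.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("empty jump set")
    _check_mass(mass)
    fractions = tuple(fractions)
    for c in fractions:
        if not 0 < c <= 1:
            raise ValueError(f"muscle fraction must be in (0, 1], got {c}")
    dens = pd.DataFrame(
        {c: powers / (mass * c) for c in fractions},
        index=pd.RangeIndex(len(powers), name="jump"),
    )
    ids = None if larva_ids is None else np.asarray(larva_ids)
    if ids is not None and len(ids) != len(powers):
        raise ValueError("larva_ids length must match powers")
    return ScenarioSweep(power_density=dens, exceeds=dens > threshold,
                         threshold=threshold, larva_ids=ids)


@dataclass(frozen=True)
class EnergeticsResult:
    """Energetics of a single jump across muscle-fraction scenarios."""

    kinetic_energy: float
    jump_power: float
    fractions: tuple
    power_density_by_fraction: dict = field(repr=False)
    exceeds_by_fraction: dict = field(repr=False)
    cot_jump: float
    cot_crawl: float
    threshold: float = POWER_DENSITY_CEILING

    @property
    def cot_ratio(self) -> float:
        return self.cot_jump / self.cot_crawl

    def power_density(self, fraction: float) -> float:
        return self.power_density_by_fraction[fraction]
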