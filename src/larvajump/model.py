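"""Per-jump and cohort model objects tying the pipeline together.

:class:`JumpModel` is built from a tracked trajectory, a phase annotation
and morphometrics; :meth:`JumpModel.fit` runs reorientation, displacement
attribution, parabola ballistics, spline differentiation, energetics and
uncertainty propagation, returning a :class:`JumpResults` that carries all
estimates and a ``summary()`` table. :func:`fit_cohort` aggregates many
fitted jumps into a :class:`CohortResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import energetics as en
from . import kinematics as kin
from . import phases as ph
from . import uncertainty as unc
from .phases import PhaseAnnotation, PhaseBreakdown
from .trajectory import TrackedTrajectory, reorient

__all__ = ["JumpModel", "JumpResults", "CohortResults", "fit_cohort"]


class JumpModel:
    """Kinematics and energetics model of a single jump.

    Parameters
    ----------
    trajectory : TrackedTrajectory
        Calibrated (metric) centre-of-mass path of the jump.
    annotation : PhaseAnnotation
        Manually recorded phase boundary frames.
    morphometrics : Morphometrics, optional
        Body mass, length and muscle measurements; cohort-average defaults.
    smoothing : float or 'gcv'
        Spline penalty for the displacement derivative curves (default
        :data:`larvajump.kinematics.DEFAULT_SMOOTHING`); ``'gcv'`` selects
        it by generalised cross-validation.
    fractions : sequence of float
        Muscle-mass-fraction scenarios for the power-density sweep.
    power_threshold : float
        Muscle power-density ceiling in W/kg (default 400).
    efficiency : float
        Muscular efficiency assumed in the jump cost of transport.
    length_uncertainty : float or None
        Absolute uncertainty of length measurements in metres (e.g. one
        pixel); None disables the uncertainty budget.
    auto_reorient : bool
        Reorient the trajectory to start at the origin and proceed in +x
        before fitting (default True).
    """

    def __init__(self, trajectory: TrackedTrajectory, annotation: PhaseAnnotation,
                 morphometrics: en.Morphometrics | None = None, *,
                 smoothing: float | str = kin.DEFAULT_SMOOTHING,
                 fractions=en.DEFAULT_FRACTIONS,
                 power_threshold: float = en.POWER_DENSITY_CEILING,
                 efficiency: float = 0.10,
                 length_uncertainty: float | None = None,
                 auto_reorient: bool = True):
        if trajectory.units != "m":
            raise ValueError("JumpModel needs a calibrated metric trajectory; "
                             "apply a ScaleCalibration first")
        annotation.check_within(len(trajectory))
        self.trajectory = trajectory
        self.annotation = annotation
        self.morphometrics = morphometrics or en.Morphometrics()
        self.smoothing = smoothing
        self.fractions = tuple(fractions)
        self.power_threshold = power_threshold
        self.efficiency = efficiency
        self.length_uncertainty = length_uncertainty
        self.auto_reorient = auto_reorient

    @classmethod
    def from_csv(cls, trajectory_path, annotation_path, calibration=None, **kwargs):
        """Build a model from a trajectory CSV and an annotation JSON."""
        from .trajectory import read_trajectory_csv

        traj = read_trajectory_csv(trajectory_path, calibration=calibration)
        ann = PhaseAnnotation.from_json(annotation_path)
        return cls(traj, ann, **kwargs)

    def fit(self) -> "JumpResults":
        traj = reorient(self.trajectory) if self.auto_reorient else self.trajectory
        m = self.morphometrics.body_mass

        cumulative = ph.cumulative_displacement(traj)
        breakdown = ph.attribute_displacement(cumulative, self.annotation,
                                              traj.frame_rate)

        x_air, y_air = kin.airborne_points(traj, self.annotation)
        fit = kin.fit_parabola(x_air, y_air)
        ballistics = kin.ballistics_summary(
            fit, body_length=self.morphometrics.body_length,
            reflected=traj.reflected)

        curves = kin.smooth_and_differentiate(
            traj.times, cumulative, smoothing=self.smoothing,
            window=kin.takeoff_window(self.annotation))

        energy = en.kinetic_energy(m, curves.v_max)
        power = en.jump_power(m, breakdown.combined_displacement,
                              breakdown.combined_duration)
        dens = {c: en.power_density(power, m, c) for c in self.fractions}
        flags = {c: dens[c] > self.power_threshold for c in self.fractions}
        energetics = en.EnergeticsResult(
            kinetic_energy=energy,
            jump_power=power,
            fractions=self.fractions,
            power_density_by_fraction=dens,
            exceeds_by_fraction=flags,
            cot_jump=en.cot_jump(energy, m, ballistics.horizontal_distance,
                                 efficiency=self.efficiency),
            cot_crawl=en.cot_crawl(m),
            threshold=self.power_threshold,
        )

        budget = None
        uncertainties = None
        if self.length_uncertainty is not None and breakdown.combined_displacement > 0:
            budget = unc.budget_for_jump(
                breakdown.combined_displacement, breakdown.combined_duration,
                traj.frame_rate, m, self.length_uncertainty,
                mass_uncertainty=self.morphometrics.mass_uncertainty)
            uncertainties = {q: unc.propagate(budget, q)
                             for q in ("velocity", "acceleration", "energy",
                                       "power", "power_density")}

        return JumpResults(
            model=self, trajectory=traj, cumulative_displacement=cumulative,
            phases=breakdown, parabola=fit, ballistics=ballistics,
            curves=curves, energetics=energetics,
            uncertainty_budget=budget, relative_uncertainties=uncertainties,
        )


@dataclass
class JumpResults:
    """Fitted estimates, diagnostics and uncertainties of one jump."""

    model: JumpModel
    trajectory: TrackedTrajectory
    cumulative_displacement: np.ndarray = field(repr=False)
    phases: PhaseBreakdown
    parabola: kin.ParabolaFit
    ballistics: kin.BallisticsSummary
    curves: kin.MotionCurves = field(repr=False)
    energetics: en.EnergeticsResult
    uncertainty_budget: unc.UncertaintyBudget | None = None
    relative_uncertainties: dict | None = None

    # convenience accessors -------------------------------------------------
    @property
    def v_max(self) -> float:
        return self.curves.v_max

    @property
    def a_max(self) -> float:
        return self.curves.a_max

    def to_row(self, larva_id=None) -> dict:
        """Flat per-jump record mirroring the cohort table column order."""
        e = self.energetics
        c_ref = self.model.morphometrics.muscle_fraction
        row = {
            "larva": larva_id,
            "loading_s": self.phases.loading_duration,
            "latch_ms": self.phases.latch_duration * 1e3,
            "launch_ms": self.phases.launch_duration * 1e3,
            "launch_dist_mm": self.phases.combined_displacement * 1e3,
            "power_W": e.jump_power,
            "power_density": e.jump_power / (self.model.morphometrics.body_mass * c_ref),
            "v_max_ms": self.v_max,
            "a_max_ms2": self.a_max,
            "energy_e7_J": e.kinetic_energy * 1e7,
            "angle_deg": self.ballistics.takeoff_angle_deg,
            "distance_mm": self.ballistics.horizontal_distance * 1e3,
            "height_mm": self.ballistics.apex_height * 1e3,
            "cot_jump": e.cot_jump,
        }
        return row

    def summary(self) -> str:
        """Human-readable per-jump summary table."""
        e = self.energetics
        b = self.ballistics
        p = self.phases
        lines = [
            "Jump kinematics and energetics",
            "=" * 46,
            f"{'samples':<30}{len(self.trajectory):>16d}",
            f"{'frame rate (fps)':<30}{self.trajectory.frame_rate:>16.0f}",
            f"{'loading duration (s)':<30}{p.loading_duration:>16.4f}",
            f"{'latch duration (ms)':<30}{p.latch_duration * 1e3:>16.3f}",
            f"{'launch duration (ms)':<30}{p.launch_duration * 1e3:>16.3f}",
            f"{'latch+launch L (mm)':<30}{p.combined_displacement * 1e3:>16.3f}",
            f"{'takeoff speed v_max (m/s)':<30}{self.v_max:>16.3f}",
            f"{'peak acceleration (m/s^2)':<30}{self.a_max:>16.1f}",
            f"{'takeoff angle (deg)':<30}{b.takeoff_angle_deg:>16.1f}",
            f"{'apex height (mm)':<30}{b.apex_height * 1e3:>16.2f}",
            f"{'horizontal distance (mm)':<30}{b.horizontal_distance * 1e3:>16.2f}",
            f"{'kinetic energy (J)':<30}{e.kinetic_energy:>16.3e}",
            f"{'jump power (W)':<30}{e.jump_power:>16.3e}",
            f"{'COT jump (J/kg/m)':<30}{e.cot_jump:>16.1f}",
            f"{'COT crawl (J/kg/m)':<30}{e.cot_crawl:>16.1f}",
            f"{'COT ratio':<30}{e.cot_ratio:>16.3f}",
            "-" * 46,
            f"power density by muscle fraction (ceiling {e.threshold:.0f} W/kg):",
        ]
        for c in e.fractions:
            flag = " *" if e.exceeds_by_fraction[c] else ""
            lines.append(f"  c = {c * 100:6.2f}%  O = {e.power_density_by_fraction[c]:10.1f} W/kg{flag}")
        if self.relative_uncertainties:
            lines.append("-" * 46)
            lines.append("relative uncertainties (first-order):")
            for q, v in self.relative_uncertainties.items():
                lines.append(f"  {q:<15}{v * 100:8.1f}%")
        return "\n".join(lines)


@dataclass
class CohortResults:
    """Per-jump table plus scenario sweep for a fitted cohort."""

    results: list = field(repr=False)
    table: pd.DataFrame
    sweep: en.ScenarioSweep

    def summary(self) -> str:
        mean = self.table.mean(numeric_only=True)
        sd = self.table.std(numeric_only=True, ddof=1)
        lines = [f"Cohort of {len(self.table)} jumps", "=" * 46]
        for col in ("v_max_ms", "angle_deg", "distance_mm", "height_mm",
                    "energy_e7_J", "power_density", "cot_jump"):
            if col in mean:
                lines.append(f"{col:<20}{mean[col]:>12.3f} +/- {sd[col]:.3f}")
        return "\n".join(lines)


def fit_cohort(models_or_jumps, morphometrics: en.Morphometrics | None = None,
               fractions=en.DEFAULT_FRACTIONS,
               threshold: float = en.POWER_DENSITY_CEILING,
               **model_kwargs) -> CohortResults:
    """Fit every jump and aggregate into a cohort table and scenario sweep.

    Accepts either prepared :class:`JumpModel` instances or synthetic jumps
    (anything with ``trajectory``/``annotation``/``larva_id`` attributes).
    """
    results = []
    larva_ids = []
    for i, item in enumerate(models_or_jumps):
        if isinstance(item, JumpModel):
            model, larva = item, i
        else:
            model = JumpModel(item.trajectory, item.annotation, morphometrics,
                              fractions=fractions, power_threshold=threshold,
                              **model_kwargs)
            larva = item.larva_id if item.larva_id is not None else i
        results.append((larva, model.fit()))
        larva_ids.append(larva)
    if not results:
        raise ValueError("empty cohort")
    table = pd.DataFrame([res.to_row(larva_id=lid) for lid, res in results])
    morpho = results[0][1].model.morphometrics
    sweep = en.scenario_sweep(
        [res.energetics.jump_power for _, res in results],
        morpho.body_mass, fractions=fractions, threshold=threshold,
        larva_ids=np.asarray(larva_ids),
    )
    return CohortResults(results=[r for _, r in results], table=table, sweep=sweep)
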