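"""Synthetic jumps with known ground truth, for end-to-end validation.

The generator emulates what high-speed filming plus centroid tracking
produces for a small jumping larva: a slow loading rise, a millisecond-scale
latch-decoupling/launch displacement ramp, and an ideal ballistic airborne
arc, sampled at the camera frame rate, quantised to the pixel grid and
perturbed with seeded Gaussian tracking jitter. Image stacks rendering the
jump as a dark elliptical blob over a light gridded background can be
produced for testing the tracking front end.

Default parameters are the observed study conditions for *Laemophloeus
biguttatus* larvae: 3,200 frames/s, takeoff speed 0.47 m/s at 79.6 deg,
0.22 s loading, 5.5 ms latch decoupling, 1.4 ms launch, 1.3 mm launch
displacement, 20 um/px scale (near-1:1 macro imaging, so the 0.5 cm grid
spans 250 px) and 0.3 px centroid noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .phases import PhaseAnnotation
from .trajectory import TrackedTrajectory

__all__ = [
    "SyntheticJumpTruth",
    "SyntheticJump",
    "generate_trajectory",
    "render_frames",
    "generate_cohort",
    "DEFAULT_COHORT_RANGES",
]


@dataclass(frozen=True)
class SyntheticJumpTruth:
    """Ground-truth parameters of one synthetic jump.

    ``pixel_scale`` may be None to disable pixel quantisation (continuous
    coordinates); ``noise_sd`` is isotropic Gaussian jitter in pixels,
    applied after quantisation.
    """

    takeoff_speed: float = 0.47          # m/s
    takeoff_angle: float = 79.6          # deg from horizontal, (0, 180)
    gravity: float = 9.81                # m/s^2
    loading_duration: float = 0.22       # s
    latch_duration: float = 5.5e-3       # s
    launch_duration: float = 1.4e-3      # s
    launch_displacement: float = 1.3e-3  # m, path length of latch+launch ramp
    loading_amplitude: float = 0.3e-3    # m, slow centroid rise while loading
    frame_rate: float = 3200.0           # frames/s
    pixel_scale: float | None = 2e-5     # m/px
    noise_sd: float = 0.3                # px
    seed: int = 0

    def __post_init__(self) -> None:
        numeric = [self.takeoff_speed, self.takeoff_angle, self.gravity,
                   self.loading_duration, self.latch_duration,
                   self.launch_duration, self.launch_displacement,
                   self.loading_amplitude, self.frame_rate, self.noise_sd]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("synthetic jump parameters must all be finite")
        if self.takeoff_speed <= 0:
            raise ValueError(f"takeoff_speed must be > 0, got {self.takeoff_speed}")
        if not 0 < self.takeoff_angle < 180:
            raise ValueError(f"takeoff_angle must be in (0, 180), got {self.takeoff_angle}")
        if self.gravity <= 0 or self.frame_rate <= 0:
            raise ValueError("gravity and frame_rate must be positive")
        for name in ("loading_duration", "latch_duration", "launch_duration",
                     "launch_displacement", "loading_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_scale is not None and not (
                self.pixel_scale > 0 and math.isfinite(self.pixel_scale)):
            raise ValueError(f"pixel_scale must be positive or None, got {self.pixel_scale}")

    # -- closed-form projectile properties -------------------------------
    @property
    def angle_rad(self) -> float:
        return math.radians(self.takeoff_angle)

    @property
    def flight_time(self) -> float:
        """Ballistic airborne duration 2 v sin(theta) / g."""
        return 2 * self.takeoff_speed * math.sin(self.angle_rad) / self.gravity

    @property
    def apex_height(self) -> float:
        """v^2 sin^2(theta) / (2 g) above the takeoff point."""
        return (self.takeoff_speed * math.sin(self.angle_rad)) ** 2 / (2 * self.gravity)

    @property
    def horizontal_range(self) -> float:
        """|v^2 sin(2 theta) / g|: range back to takeoff height."""
        return abs(self.takeoff_speed ** 2
                   * math.sin(2 * self.angle_rad) / self.gravity)

    def specific_energy_balance(self) -> tuple[float, float]:
        """(1/2 v^2, g h_apex + 1/2 (v cos theta)^2) — equal by construction."""
        lhs = 0.5 * self.takeoff_speed ** 2
        rhs = (self.gravity * self.apex_height
               + 0.5 * (self.takeoff_speed * math.cos(self.angle_rad)) ** 2)
        return lhs, rhs

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({k: getattr(self, k) for k in self.__dataclass_fields__}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticJumpTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class SyntheticJump:
    """A generated jump: truth, its trajectory and phase annotation."""

    truth: SyntheticJumpTruth
    trajectory: TrackedTrajectory
    annotation: PhaseAnnotation
    larva_id: int | None = None
    frames: np.ndarray | None = field(default=None, repr=False)
    #: (x, y) pixel offset of the rendered frame origin, such that
    #: trajectory_px - origin gives in-frame coordinates; set by render_frames.
    render_origin_px: tuple[float, float] | None = None


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3 - 2 * u)


def generate_trajectory(truth: SyntheticJumpTruth) -> SyntheticJump:
    """Generate the centre-of-mass trajectory a tracker would produce.

    Loading rises the centroid by ``loading_amplitude`` along y on a
    smoothstep ramp; the pooled latch+launch window displaces it by
    ``launch_displacement`` along the takeoff direction on a power-law ramp
    s(tau) = L (tau/T)^q with q = v T / L, which ends with speed exactly v
    so the transition into ballistic flight is velocity-continuous; the
    airborne samples follow ideal projectile motion until the centroid
    returns to takeoff height. Coordinates are then quantised to the pixel
    grid and perturbed with seeded Gaussian noise.
    """
    fps = truth.frame_rate
    n_load = max(1, round(truth.loading_duration * fps))
    n_latch = round(truth.latch_duration * fps)
    n_launch = round(truth.launch_duration * fps)
    if n_latch + n_launch < 1:
        n_launch = 1  # power window must span at least one frame interval
    n_ll = n_latch + n_launch
    n_air = max(2, math.floor(truth.flight_time * fps))

    a0 = n_load + n_ll          # first airborne frame = takeoff instant
    landing = a0 + n_air
    n = landing + 1

    x = np.zeros(n)
    y = np.zeros(n)

    # loading: slow smooth rise, negligible speed
    k_load = np.arange(n_load + 1)
    y[: n_load + 1] = truth.loading_amplitude * _smoothstep(k_load / n_load)

    # latch + launch: monotone power-law displacement ramp along takeoff dir
    direction = np.array([math.cos(truth.angle_rad), math.sin(truth.angle_rad)])
    T = n_ll / fps
    L = truth.launch_displacement
    tau = np.arange(n_ll + 1) / fps
    if L > 0:
        q = truth.takeoff_speed * T / L
        s = L * (tau / T) ** q
    else:
        s = np.zeros(n_ll + 1)
    x[n_load: a0 + 1] = x[n_load] + direction[0] * s
    y[n_load: a0 + 1] = y[n_load] + direction[1] * s

    # airborne: ideal projectile from the takeoff point
    t_air = np.arange(n_air + 1) / fps
    vx = truth.takeoff_speed * direction[0]
    vy = truth.takeoff_speed * direction[1]
    x[a0:] = x[a0] + vx * t_air
    y[a0:] = y[a0] + vy * t_air - 0.5 * truth.gravity * t_air ** 2

    # pixel quantisation, then seeded tracking jitter (both in px units)
    if truth.pixel_scale is not None:
        ps = truth.pixel_scale
        x = np.round(x / ps) * ps
        y = np.round(y / ps) * ps
        if truth.noise_sd > 0:
            rng = np.random.default_rng(truth.seed)
            x = x + rng.normal(0, truth.noise_sd * ps, n)
            y = y + rng.normal(0, truth.noise_sd * ps, n)

    trajectory = TrackedTrajectory(
        times=np.arange(n) / fps, x=x, y=y,
        frame_rate=fps, units="m", source="synthetic",
    )
    annotation = PhaseAnnotation(
        loading_start=0,
        latch_start=n_load,
        launch_start=n_load + n_latch,
        airborne_start=a0,
        landing=landing,
    )
    return SyntheticJump(truth=truth, trajectory=trajectory, annotation=annotation)


def render_frames(jump: SyntheticJump, blob_diameter: float = 9.0,
                  grid_spacing_px: int = 50, shape: tuple[int, int] | None = None,
                  margin: int = 8, aspect: float = 1.5,
                  foreground: int = 25, background: int = 230,
                  grid_value: int = 205) -> SyntheticJump:
    """Render the jump as an 8-bit grayscale image stack.

    Each frame shows a dark, anti-aliased elliptical blob (major axis
    ``aspect`` times the minor, horizontal) centred on the true centroid,
    over a light background overlaid with a faint calibration grid of
    ``grid_spacing_px`` pixels. The centroid of the thresholded blob mask
    matches the trajectory point to within half a pixel.

    Returns a copy of the jump with ``frames`` attached.
    """
    if blob_diameter < 3:
        raise ValueError(f"blob_diameter must be >= 3 px, got {blob_diameter}")
    ps = jump.truth.pixel_scale
    if ps is None:
        raise ValueError("cannot render a jump generated without a pixel scale")
    x_px = jump.trajectory.x / ps
    y_px = jump.trajectory.y / ps

    ax = aspect * blob_diameter / 2.0  # semi-axis along x
    ay = blob_diameter / 2.0
    pad = int(math.ceil(max(ax, ay))) + margin
    if shape is None:
        x_off = math.floor(x_px.min()) - pad
        y_off = math.floor(y_px.min()) - pad
        width = int(math.ceil(x_px.max() - x_off)) + pad + 1
        height = int(math.ceil(y_px.max() - y_off)) + pad + 1
        x_px = x_px - x_off
        y_px = y_px - y_off
    else:
        height, width = shape
        x_off = y_off = 0

    n = len(x_px)
    stack = np.empty((n, height, width), dtype=np.uint8)
    base = np.full((height, width), background, dtype=np.uint8)
    base[::grid_spacing_px, :] = grid_value
    base[:, ::grid_spacing_px] = grid_value

    rows = np.arange(height, dtype=float)
    cols = np.arange(width, dtype=float)
    for i in range(n):
        cx, cy = x_px[i], y_px[i]
        crow = (height - 1) - cy  # y up -> image row
        if not (ax <= cx <= width - 1 - ax and ay <= crow <= height - 1 - ay):
            raise ValueError(
                f"trajectory exits frame bounds at frame {i}: "
                f"centroid ({cx:.1f}, {cy:.1f}) px in a {width}x{height} frame"
            )
        frame = base.astype(float).copy()
        r0 = max(0, int(crow - ay) - 2)
        r1 = min(height, int(crow + ay) + 3)
        c0 = max(0, int(cx - ax) - 2)
        c1 = min(width, int(cx + ax) + 3)
        rr, cc = np.meshgrid(rows[r0:r1], cols[c0:c1], indexing="ij")
        radial = np.sqrt(((cc - cx) / ax) ** 2 + ((rr - crow) / ay) ** 2)
        # anti-aliased coverage from the approximate signed edge distance
        dist = (radial - 1.0) * min(ax, ay)
        coverage = np.clip(0.5 - dist, 0.0, 1.0)
        patch = frame[r0:r1, c0:c1]
        frame[r0:r1, c0:c1] = patch * (1 - coverage) + foreground * coverage
        stack[i] = np.round(frame).astype(np.uint8)
    return replace(jump, frames=stack, render_origin_px=(float(x_off), float(y_off)))


def write_jump(jump: SyntheticJump, directory, stem: str = "jump") -> None:
    """Write a synthetic jump to ``directory``: trajectory CSV, truth and
    annotation JSON sidecars, and (if rendered) a multi-page TIFF stack."""
    import os

    from .trajectory import write_trajectory_csv

    os.makedirs(directory, exist_ok=True)
    write_trajectory_csv(jump.trajectory, os.path.join(directory, f"{stem}_trajectory.csv"))
    jump.truth.to_json(os.path.join(directory, f"{stem}_truth.json"))
    jump.annotation.to_json(os.path.join(directory, f"{stem}_annotation.json"))
    if jump.frames is not None:
        import tifffile

        tifffile.imwrite(os.path.join(directory, f"{stem}_frames.tif"), jump.frames)


#: Per-jump parameter ranges emulating the observed cohort spread:
#: takeoff speeds 0.14-0.87 m/s, takeoff angles 30-110 deg, loading
#: 0.03-0.68 s, latch decoupling 0.6-9 ms, launch 0.3-3.4 ms.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "takeoff_speed": (0.14, 0.87),
    "takeoff_angle": (30.0, 110.0),
    "loading_duration": (0.03, 0.68),
    "latch_duration": (0.6e-3, 9e-3),
    "launch_duration": (0.3e-3, 3.4e-3),
}


def generate_cohort(n_larvae: int, jumps_per_larva=3, parameter_ranges=None,
                    seed: int = 0, noise_sd: float | None = None,
                    pixel_scale: float | None = 2e-5) -> list[SyntheticJump]:
    """Generate a reproducible cohort of synthetic jumps.

    Parameters
    ----------
    n_larvae : int
        Number of individuals (>= 1).
    jumps_per_larva : int or (lo, hi)
        Fixed count, or an inclusive range drawn per larva.
    parameter_ranges : dict, optional
        ``field -> (lo, hi)`` uniform ranges for truth fields, overriding
        :data:`DEFAULT_COHORT_RANGES`. Point ranges pin a parameter. Unless
        ``launch_displacement`` is given a range, it is drawn as a fraction
        0.35-0.8 of ``v * t`` of the latch+launch window, keeping the
        pre-airborne ramp kinematically plausible.
    seed : int
        Seeds all draws; generation is bit-reproducible for a fixed seed.
    noise_sd, pixel_scale :
        Override the corresponding truth fields for the whole cohort
        (``noise_sd=None`` keeps the default 0.3 px).

    Timing parameters are drawn once per larva; takeoff speed and angle
    vary per jump.
    """
    if n_larvae < 1:
        raise ValueError(f"n_larvae must be >= 1, got {n_larvae}")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if parameter_ranges:
        for k, (lo, hi) in parameter_ranges.items():
            if hi < lo:
                raise ValueError(f"empty range for {k!r}: ({lo}, {hi})")
            ranges[k] = (lo, hi)
    rng = np.random.default_rng(seed)
    per_larva_fields = ("loading_duration", "latch_duration", "launch_duration")
    jumps: list[SyntheticJump] = []
    for larva in range(n_larvae):
        larva_params = {f: rng.uniform(*ranges[f]) for f in per_larva_fields}
        if isinstance(jumps_per_larva, int):
            n_jumps = jumps_per_larva
        else:
            lo, hi = jumps_per_larva
            n_jumps = int(rng.integers(lo, hi + 1))
        for _ in range(n_jumps):
            params = dict(larva_params)
            params["takeoff_speed"] = rng.uniform(*ranges["takeoff_speed"])
            params["takeoff_angle"] = rng.uniform(*ranges["takeoff_angle"])
            window = params["latch_duration"] + params["launch_duration"]
            if "launch_displacement" in ranges:
                params["launch_displacement"] = rng.uniform(*ranges["launch_displacement"])
            else:
                share = rng.uniform(0.35, 0.8)
                params["launch_displacement"] = share * params["takeoff_speed"] * window
            for extra in ("gravity", "loading_amplitude", "frame_rate", "noise_sd"):
                if extra in ranges:
                    params[extra] = rng.uniform(*ranges[extra])
            if noise_sd is not None:
                params["noise_sd"] = noise_sd
            truth = SyntheticJumpTruth(
                pixel_scale=pixel_scale,
                seed=int(rng.integers(2 ** 31)),
                **params,
            )
            jump = generate_trajectory(truth)
            jumps.append(replace(jump, larva_id=larva))
    return jumps
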