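"""Jump phase annotations, durations and per-phase displacement attribution.

A jump is segmented into four phases: loading (slow body arching while the
legs grip the substrate), latch decoupling (legs progressively release),
launch (stored elastic energy converts to kinetic energy) and airborne.
Latch decoupling and launch are pooled into a single window for power
estimation, since in practice the two heavily overlap; pooling biases power
estimates conservatively low.

Phase windows are half-open ``[start, end)`` in frame indices: a boundary
frame belongs to the later phase, which makes per-phase displacement shares
sum exactly to the total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .trajectory import TrackedTrajectory

__all__ = [
    "PhaseAnnotation",
    "PhaseBreakdown",
    "phase_durations",
    "cumulative_displacement",
    "attribute_displacement",
    "detect_annotation",
]

_FIELDS = ("loading_start", "latch_start", "launch_start", "airborne_start", "landing")


@dataclass(frozen=True)
class PhaseAnnotation:
    """Frame indices of phase boundaries (0-based, half-open windows).

    ``loading_start < latch_start <= launch_start <= airborne_start < landing``.
    ``latch_start`` is the frame where the first leg begins to lose contact,
    ``launch_start`` where the last leg leaves the ground, ``airborne_start``
    where all body-substrate contact has ceased.
    """

    loading_start: int
    latch_start: int
    launch_start: int
    airborne_start: int
    landing: int

    def __post_init__(self) -> None:
        vals = [getattr(self, f) for f in _FIELDS]
        if any(int(v) != v for v in vals):
            raise ValueError("phase boundaries must be integer frame indices")
        for f, v in zip(_FIELDS, vals):
            object.__setattr__(self, f, int(v))
        pairs = [
            ("loading_start", "latch_start", True),
            ("latch_start", "launch_start", False),
            ("launch_start", "airborne_start", False),
            ("airborne_start", "landing", True),
        ]
        for lo, hi, strict in pairs:
            a, b = getattr(self, lo), getattr(self, hi)
            if (a >= b) if strict else (a > b):
                op = "<" if strict else "<="
                raise ValueError(f"phase ordering violated: need {lo} {op} {hi}, "
                                 f"got {a} and {b}")
        if self.loading_start < 0:
            raise ValueError("loading_start must be >= 0")

    def check_within(self, n_frames: int) -> None:
        if self.landing >= n_frames:
            raise ValueError(
                f"annotation landing frame {self.landing} outside trajectory "
                f"of {n_frames} frames"
            )

    @classmethod
    def from_json(cls, path) -> "PhaseAnnotation":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        missing = set(_FIELDS) - set(data)
        if missing:
            raise ValueError(f"annotation file missing fields: {sorted(missing)}")
        return cls(**{f: data[f] for f in _FIELDS})

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({f: getattr(self, f) for f in _FIELDS}, fh, indent=1)


@dataclass(frozen=True)
class PhaseBreakdown:
    """Durations (s) and path displacements (m) of the four phases.

    ``combined_duration`` / ``combined_displacement`` are the pooled
    latch-decoupling + launch window used by the power calculation
    (the t and L of P = m L^2 / t^3).
    """

    loading_duration: float
    latch_duration: float
    launch_duration: float
    airborne_duration: float
    loading_displacement: float = float("nan")
    latch_displacement: float = float("nan")
    launch_displacement: float = float("nan")
    airborne_displacement: float = float("nan")

    @property
    def combined_duration(self) -> float:
        return self.latch_duration + self.launch_duration

    @property
    def combined_displacement(self) -> float:
        return self.latch_displacement + self.launch_displacement

    @property
    def total_displacement(self) -> float:
        return (self.loading_displacement + self.latch_displacement
                + self.launch_displacement + self.airborne_displacement)


def phase_durations(annotation: PhaseAnnotation, frame_rate: float) -> PhaseBreakdown:
    """Phase durations from boundary frames: (end - start) / frame_rate."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    a = annotation
    return PhaseBreakdown(
        loading_duration=(a.latch_start - a.loading_start) / frame_rate,
        latch_duration=(a.launch_start - a.latch_start) / frame_rate,
        launch_duration=(a.airborne_start - a.launch_start) / frame_rate,
        airborne_duration=(a.landing - a.airborne_start) / frame_rate,
    )


def cumulative_displacement(trajectory: TrackedTrajectory) -> np.ndarray:
    """Per-frame cumulative path length (metres), starting at 0.

    Increment at frame i is the Euclidean distance between samples i-1 and
    i, so the series is monotone non-decreasing and its final value is at
    least the straight-line start-to-end distance.
    """
    steps = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    return np.concatenate([[0.0], np.cumsum(steps)])


def attribute_displacement(cumulative: np.ndarray, annotation: PhaseAnnotation,
                           frame_rate: float) -> PhaseBreakdown:
    """Attribute cumulative displacement to phases and compute durations.

    Each phase receives ``cumulative[end] - cumulative[start]`` of path
    length (half-open windows), so the four shares sum exactly to the total
    displacement accrued between loading start and landing.
    """
    cumulative = np.asarray(cumulative, dtype=float)
    annotation.check_within(len(cumulative))
    durations = phase_durations(annotation, frame_rate)
    a = annotation
    return PhaseBreakdown(
        loading_duration=durations.loading_duration,
        latch_duration=durations.latch_duration,
        launch_duration=durations.launch_duration,
        airborne_duration=durations.airborne_duration,
        loading_displacement=cumulative[a.latch_start] - cumulative[a.loading_start],
        latch_displacement=cumulative[a.launch_start] - cumulative[a.latch_start],
        launch_displacement=cumulative[a.airborne_start] - cumulative[a.launch_start],
        airborne_displacement=cumulative[a.landing] - cumulative[a.airborne_start],
    )


def detect_annotation(trajectory: TrackedTrajectory, speed_fraction: float = 0.2,
                      landing_index: int | None = None) -> PhaseAnnotation:
    """Heuristic phase detector (experimental).

    Phase boundaries are normally manual inputs; this velocity-threshold
    change-point heuristic exists only for quick exploration. It marks
    latch start at the first frame whose instantaneous speed exceeds
    ``speed_fraction`` of the peak speed, and airborne start at the peak
    itself; the latch/launch split is placed at their midpoint.
    """
    speed = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y)) * trajectory.frame_rate
    peak = int(np.argmax(speed))
    thresh = speed_fraction * speed[peak]
    moving = np.flatnonzero(speed[: peak + 1] > thresh)
    latch = int(moving[0]) if len(moving) else max(peak - 1, 1)
    latch = max(latch, 1)
    airborne = max(peak + 1, latch)
    launch = (latch + airborne) // 2
    landing = len(trajectory) - 1 if landing_index is None else landing_index
    return PhaseAnnotation(0, latch, launch, airborne, landing)
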