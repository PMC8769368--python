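"""Calibrated centre-of-mass trajectories and their on-disk CSV dialect.

A :class:`TrackedTrajectory` is the common currency of the package: a
uniformly sampled (x, y) path of one jump, in metres (or raw pixels before
calibration), with y increasing upward so that gravity acts along -y.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrackedTrajectory",
    "ScaleCalibration",
    "calibrate_scale",
    "apply_calibration",
    "reorient",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

_VALID_UNITS = ("m", "px")
_VALID_SOURCES = ("tracked", "imported", "synthetic")


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel-to-metric calibration derived from a grid of known spacing.

    Parameters
    ----------
    meters_per_pixel : float
        Metric size of one pixel, ``grid_spacing_m / grid_spacing_px``.
    grid_spacing_m : float
        Physical grid spacing in metres (default 5 mm).
    grid_spacing_px : float
        Measured grid spacing in pixels.
    uncertainty_m : float
        Measurement precision of the grid spacing itself, in metres
        (default 1 um, the precision of a calibrated measuring microscope).
    """

    meters_per_pixel: float
    grid_spacing_m: float = 5e-3
    grid_spacing_px: float = float("nan")
    uncertainty_m: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.meters_per_pixel > 0 and np.isfinite(self.meters_per_pixel)):
            raise ValueError(
                f"meters_per_pixel must be positive and finite, got {self.meters_per_pixel}"
            )


def calibrate_scale(grid_spacing_px: float, grid_spacing_m: float = 5e-3,
                    uncertainty_m: float = 1e-6) -> ScaleCalibration:
    """Build a :class:`ScaleCalibration` from a measured grid spacing.

    >>> calibrate_scale(50, 0.005).meters_per_pixel
    0.0001
    """
    if not (grid_spacing_px > 0 and np.isfinite(grid_spacing_px)):
        raise ValueError(f"grid_spacing_px must be positive, got {grid_spacing_px}")
    if not (grid_spacing_m > 0 and np.isfinite(grid_spacing_m)):
        raise ValueError(f"grid_spacing_m must be positive, got {grid_spacing_m}")
    return ScaleCalibration(
        meters_per_pixel=grid_spacing_m / grid_spacing_px,
        grid_spacing_m=grid_spacing_m,
        grid_spacing_px=grid_spacing_px,
        uncertainty_m=uncertainty_m,
    )


@dataclass(frozen=True)
class TrackedTrajectory:
    """Uniformly sampled centre-of-mass path of one jump.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing with uniform spacing
        ``1 / frame_rate``.
    x, y : ndarray
        Coordinates; metres when ``units == 'm'``, pixels when ``'px'``.
        y increases upward (image row axis is inverted at import time).
    frame_rate : float
        Frames per second.
    units : str
        ``'m'`` or ``'px'``.
    source : str
        ``'tracked'`` (from an image stack), ``'imported'`` (from CSV) or
        ``'synthetic'``.
    reflected : bool
        True if the x axis was mirrored during reorientation.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    units: str = "m"
    source: str = "tracked"
    reflected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("times, x and y must have equal length")
        if len(t) < 3:
            raise ValueError(f"trajectory needs at least 3 samples, got {len(t)}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
            raise ValueError("trajectory contains non-finite coordinates or times")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        expected = 1.0 / self.frame_rate
        if not np.allclose(dt, expected, rtol=1e-6, atol=1e-12):
            raise ValueError(
                "times are not uniform at 1/frame_rate "
                f"(expected spacing {expected:.6g})"
            )
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")
        if self.source not in _VALID_SOURCES:
            raise ValueError(f"source must be one of {_VALID_SOURCES}, got {self.source!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "t_s": self.times, "x": self.x, "y": self.y}
        )


def apply_calibration(trajectory: TrackedTrajectory,
                      calibration: ScaleCalibration) -> TrackedTrajectory:
    """Convert a pixel-unit trajectory to metres."""
    if trajectory.units != "px":
        raise ValueError("apply_calibration expects a pixel-unit trajectory")
    s = calibration.meters_per_pixel
    return replace(trajectory, x=trajectory.x * s, y=trajectory.y * s, units="m")


def reorient(trajectory: TrackedTrajectory) -> TrackedTrajectory:
    """Translate a jump to start at the origin and proceed in +x.

    The first sample is moved to (0, 0). If the net horizontal displacement
    is negative the x axis is mirrored (and ``reflected`` recorded) so every
    jump proceeds in the positive x direction; y is already up, so gravity
    acts along -y. The transform is rigid (a translation plus at most one
    reflection), hence all inter-point distances are preserved and the
    operation is idempotent.
    """
    x = trajectory.x - trajectory.x[0]
    y = trajectory.y - trajectory.y[0]
    net_dx = x[-1] - x[0]
    reflected = trajectory.reflected
    if net_dx < 0:
        x = -x
        reflected = not reflected
    elif net_dx == 0:
        warnings.warn("zero net horizontal displacement; trajectory left unreflected",
                      stacklevel=2)
    return replace(trajectory, x=x, y=y, reflected=reflected)


# ---------------------------------------------------------------------------
# CSV dialect: '#'-prefixed key: value metadata lines, then frame,t_s,x,y.
# Floats are written with shortest round-trippable repr, so one write/read
# cycle reproduces coordinates bit-exactly.

def write_trajectory_csv(trajectory: TrackedTrajectory, path) -> None:
    """Write a trajectory in the package's CSV dialect (UTF-8, '.' decimal)."""
    df = trajectory.to_dataframe()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# larvajump trajectory v1\n")
        fh.write(f"# frame_rate_hz: {trajectory.frame_rate!r}\n")
        fh.write(f"# units: {trajectory.units}\n")
        fh.write(f"# source: {trajectory.source}\n")
        fh.write(f"# reflected: {int(trajectory.reflected)}\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path, calibration: ScaleCalibration | None = None) -> TrackedTrajectory:
    """Read a trajectory CSV; optionally calibrate a pixel-unit file to metres.

    Raises a descriptive :class:`ValueError` on missing columns, duplicated
    frame indices or non-uniform frame spacing.
    """
    meta: dict[str, str] = {}
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)), float_precision="round_trip")
    required = {"frame", "t_s", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    frames = df["frame"].to_numpy()
    if len(np.unique(frames)) != len(frames):
        raise ValueError("trajectory CSV has duplicated frame indices")
    if not np.array_equal(np.sort(frames), frames):
        raise ValueError("trajectory CSV frames are not sorted")
    if len(frames) >= 2 and not np.all(np.diff(frames) == 1):
        raise ValueError("trajectory CSV has non-consecutive frame indices")
    if "frame_rate_hz" not in meta:
        raise ValueError("trajectory CSV lacks '# frame_rate_hz:' metadata")
    frame_rate = float(meta["frame_rate_hz"])
    units = meta.get("units", "m")
    traj = TrackedTrajectory(
        times=df["t_s"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        frame_rate=frame_rate,
        units=units,
        source="imported",
        reflected=bool(int(meta.get("reflected", "0"))),
    )
    if calibration is not None and units == "px":
        traj = apply_calibration(traj, calibration)
    return traj
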