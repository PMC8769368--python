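"""Ballistic characterisation of the airborne phase and spline kinematics.

The airborne arc is summarised by a least-squares parabola
``y = a x^2 + b x + c``; the apex height is the vertex *y* coordinate
``c - b^2/(4a)``, the horizontal range the larger real root, and the
takeoff angle ``arctan(b)`` (the slope of the arc at its x-intercept at the
origin after reorientation). Takeoff velocity and acceleration come from a
penalised smoothing spline of cumulative displacement: the analytic first
and second derivatives are maximised over the pooled latch + launch window
extended one frame into the airborne phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .phases import PhaseAnnotation
from .trajectory import TrackedTrajectory

__all__ = [
    "ParabolaFit",
    "BallisticsSummary",
    "MotionCurves",
    "DEFAULT_SMOOTHING",
    "fit_parabola",
    "apex_height",
    "horizontal_range",
    "takeoff_angle",
    "ballistics_summary",
    "smooth_and_differentiate",
    "takeoff_window",
]

#: Default spline penalty on the integrated squared second derivative of
#: displacement. A cubic smoothing spline's equivalent kernel bandwidth
#: scales as lam^(1/4) (~6 ms here): wide enough to suppress sub-millisecond
#: tracking jitter, narrow enough to resolve the millisecond-scale launch
#: transient that sets the takeoff velocity. Generalised cross-validation
#: is deliberately not the default: the long quasi-static loading phase
#: dominates a GCV fit and systematically oversmooths the launch window.
DEFAULT_SMOOTHING = 1e-9


@dataclass(frozen=True)
class ParabolaFit:
    """Quadratic fit y = a x^2 + b x + c to the airborne arc (metres)."""

    a: float
    b: float
    c: float
    rss: float
    n_points: int


@dataclass(frozen=True)
class BallisticsSummary:
    """Apex height h, horizontal distance d and takeoff angle of one jump."""

    apex_height: float
    horizontal_distance: float
    takeoff_angle_deg: float
    body_lengths_horizontal: float = float("nan")
    body_lengths_vertical: float = float("nan")


@dataclass(frozen=True)
class MotionCurves:
    """Smoothed displacement with analytic derivatives on the same time base."""

    times: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    v_max: float
    a_max: float
    smoothing_parameter: float | str


def fit_parabola(x: np.ndarray, y: np.ndarray) -> ParabolaFit:
    """Least-squares quadratic through the airborne (x, y) points.

    Exact on noiseless quadratic input. Raises if fewer than 3 points, all
    x equal, or the fitted arc does not open downward (``a >= 0``) — the
    latter also catches collinear points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 airborne points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("all x coordinates equal; cannot fit y(x) parabola")
    a, b, c = np.polyfit(x, y, 2)
    rss = float(np.sum((np.polyval([a, b, c], x) - y) ** 2))
    if a >= 0:
        raise ValueError(f"no downward arc: fitted leading coefficient a = {a:.4g} >= 0")
    return ParabolaFit(a=float(a), b=float(b), c=float(c), rss=rss, n_points=len(x))


def apex_height(fit: ParabolaFit, convention: str = "vertex_y") -> float:
    """Apex height of the arc.

    ``'vertex_y'`` (default) returns the vertex y coordinate
    ``c - b^2/(4a)``. ``'vertex_x'`` returns ``-b/(2a)``, the vertex x
    coordinate, offered only for comparison with conventions that quote it.
    """
    if fit.a >= 0:
        raise ValueError("apex undefined: parabola does not open downward")
    if convention == "vertex_y":
        return fit.c - fit.b ** 2 / (4 * fit.a)
    if convention == "vertex_x":
        return -fit.b / (2 * fit.a)
    raise ValueError(f"unknown convention {convention!r}")


def horizontal_range(fit: ParabolaFit) -> float:
    """Horizontal distance: the larger real root of a x^2 + b x + c = 0."""
    if fit.a >= 0:
        raise ValueError("range undefined: parabola does not open downward")
    disc = fit.b ** 2 - 4 * fit.a * fit.c
    if disc < 0:
        raise ValueError("no real x-intercept: arc never returns to y = 0")
    # a < 0, so the '-' branch of the quadratic formula is the larger root
    return (-fit.b - math.sqrt(disc)) / (2 * fit.a)


def takeoff_angle(fit: ParabolaFit, reflected: bool = False,
                  convention: str = "reoriented") -> float:
    """Takeoff angle in degrees from horizontal, ``arctan(b)``.

    After reorientation every jump proceeds in +x, so the default
    convention reports an angle in (0, 90]. With ``convention='raw'`` and a
    trajectory that was mirrored during reorientation, the angle in the
    original camera frame, ``180 - arctan(b)``, is returned instead.
    """
    alpha = math.degrees(math.atan(fit.b))
    if convention == "raw" and reflected:
        return 180.0 - alpha
    if convention not in ("reoriented", "raw"):
        raise ValueError(f"unknown convention {convention!r}")
    return alpha


def ballistics_summary(fit: ParabolaFit, body_length: float | None = None,
                       reflected: bool = False) -> BallisticsSummary:
    """Bundle apex height, range and takeoff angle; optionally body-length scaled."""
    h = apex_height(fit)
    d = horizontal_range(fit)
    return BallisticsSummary(
        apex_height=h,
        horizontal_distance=d,
        takeoff_angle_deg=takeoff_angle(fit, reflected=reflected),
        body_lengths_horizontal=d / body_length if body_length else float("nan"),
        body_lengths_vertical=h / body_length if body_length else float("nan"),
    )


def takeoff_window(annotation: PhaseAnnotation) -> slice:
    """Index window for v_max/a_max: pooled latch+launch plus one airborne frame.

    The first airborne sample is the takeoff instant itself; one further
    frame is included to tolerate single-frame annotation slack.
    """
    return slice(annotation.latch_start, annotation.airborne_start + 2)


def smooth_and_differentiate(times: np.ndarray, displacement: np.ndarray,
                             smoothing: float | str = DEFAULT_SMOOTHING,
                             window: slice | None = None) -> MotionCurves:
    """Penalised smoothing spline of cumulative displacement with derivatives.

    Parameters
    ----------
    times, displacement : ndarray
        Uniform time base (s) and the monotone cumulative path length (m).
    smoothing : float or 'gcv'
        Penalty weight ``lam`` on the integrated squared second derivative
        of the spline (default :data:`DEFAULT_SMOOTHING`); ``'gcv'``
        selects it by generalised cross-validation instead.
    window : slice or None
        Index window over which ``v_max`` and ``a_max`` are taken
        (typically :func:`takeoff_window`); the whole series if None.

    Velocity and acceleration are the analytic first and second derivatives
    of the fitted spline evaluated on the input time base.
    """
    times = np.asarray(times, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if len(times) < 7:
        raise ValueError(f"need at least 7 samples to smooth, got {len(times)}")
    if len(times) != len(displacement):
        raise ValueError("times and displacement must have equal length")
    if smoothing != "gcv" and not (isinstance(smoothing, (int, float)) and smoothing > 0):
        raise ValueError(f"smoothing must be a positive number or 'gcv', got {smoothing!r}")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time base must be uniform")

    lam = None if smoothing == "gcv" else float(smoothing)
    spline = make_smoothing_spline(times, displacement, lam=lam)
    smoothed = spline(times)
    velocity = spline.derivative(1)(times)
    acceleration = spline.derivative(2)(times)
    win = window if window is not None else slice(None)
    v_win = velocity[win]
    a_win = acceleration[win]
    if len(v_win) == 0:
        raise ValueError("empty v_max window")
    return MotionCurves(
        times=times,
        displacement=smoothed,
        velocity=velocity,
        acceleration=acceleration,
        v_max=float(np.max(v_win)),
        a_max=float(np.max(a_win)),
        smoothing_parameter=smoothing,
    )


def airborne_points(trajectory: TrackedTrajectory,
                    annotation: PhaseAnnotation) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) samples of the airborne phase, inclusive of takeoff and landing."""
    annotation.check_within(len(trajectory))
    sl = slice(annotation.airborne_start, annotation.landing + 1)
    return trajectory.x[sl], trajectory.y[sl]
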