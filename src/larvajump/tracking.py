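"""Threshold-based centroid tracking of a dark (or light) jumper in an image stack.

Each 8-bit grayscale frame is binarised at a fixed global threshold, the
largest 8-connected foreground component is taken as the animal, and its
binary-mask area centroid is the per-frame centre-of-mass estimate. Equal
largest components are disambiguated by proximity to the previous centroid.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

from .trajectory import TrackedTrajectory

__all__ = ["track_centroids"]


def _frame_centroid(frame: np.ndarray, threshold: float, polarity: str,
                    prev: tuple[float, float] | None, index: int) -> tuple[float, float]:
    if polarity == "dark-on-light":
        mask = frame < threshold
    else:
        mask = frame > threshold
    if not mask.any():
        raise ValueError(f"no foreground pixels in frame {index} at threshold {threshold}")
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    max_area = areas.max()
    candidates = np.flatnonzero(areas == max_area)
    if len(candidates) > 1:
        warnings.warn(
            f"frame {index}: {len(candidates)} equal-size components; "
            "tie-broken by proximity to previous centroid",
            stacklevel=3,
        )
        cents = [np.argwhere(labels == lab).mean(axis=0) for lab in candidates]
        if prev is None:
            chosen = 0
        else:
            prev_rc = np.array(prev)
            chosen = int(np.argmin([np.hypot(*(c - prev_rc)) for c in cents]))
        r, c = cents[chosen]
    else:
        r, c = np.argwhere(labels == candidates[0]).mean(axis=0)
    return float(r), float(c)


def track_centroids(frames: np.ndarray, threshold: float, polarity: str = "dark-on-light",
                    frame_rate: float = 3200.0) -> TrackedTrajectory:
    """Track the blob centroid across a stack of 8-bit grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Image stack, one grayscale frame per time point.
    threshold : float
        Global intensity threshold in [0, 255]. With ``'dark-on-light'``
        polarity foreground is ``pixel < threshold``; with
        ``'light-on-dark'`` it is ``pixel > threshold``.
    polarity : str
        ``'dark-on-light'`` (default) or ``'light-on-dark'``.
    frame_rate : float
        Frames per second of the recording.

    Returns
    -------
    TrackedTrajectory
        Pixel-unit trajectory (``units='px'``) with y up: ``x`` is the
        column coordinate and ``y = (H - 1) - row``.

    Raises
    ------
    ValueError
        If the stack is empty, the threshold is out of range, or a frame
        contains no foreground pixels (the frame index is named).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError(f"expected a non-empty (T, H, W) stack, got shape {frames.shape}")
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    if polarity not in ("dark-on-light", "light-on-dark"):
        raise ValueError(f"unknown polarity {polarity!r}")

    n, height, _ = frames.shape
    xs = np.empty(n)
    ys = np.empty(n)
    prev: tuple[float, float] | None = None
    for i in range(n):
        r, c = _frame_centroid(frames[i], threshold, polarity, prev, i)
        prev = (r, c)
        xs[i] = c
        ys[i] = (height - 1) - r
    return TrackedTrajectory(
        times=np.arange(n) / frame_rate,
        x=xs,
        y=ys,
        frame_rate=frame_rate,
        units="px",
        source="tracked",
    )
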