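"""Cohort summary tables and report figures.

``summarize_cohort`` reduces a per-jump table to per-larva means with
(min-max) ranges plus a cohort mean +/- SD row; ``render_report`` writes
the standard three figures (trajectory overlay, kinematic curves with phase
shading, power density vs muscle fraction with the 400 W/kg ceiling) and a
byte-stable CSV of the summary table.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .energetics import POWER_DENSITY_CEILING

__all__ = ["summarize_cohort", "render_report"]


def summarize_cohort(table: pd.DataFrame, by: str = "larva",
                     metrics=None) -> pd.DataFrame:
    """Per-larva mean/min/max for every metric plus a cohort mean +/- SD row.

    ``table`` is a per-jump DataFrame (one row per jump) with a ``by``
    column identifying the larva. The returned frame has one row per larva
    with ``<metric>_mean``, ``<metric>_min`` and ``<metric>_max`` columns
    and a final ``cohort`` row where the min/max slots carry mean - SD and
    mean + SD (sample SD, n-1 denominator).
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    if by not in table.columns:
        raise ValueError(f"column {by!r} not in table")
    if metrics is None:
        metrics = [c for c in table.columns
                   if c != by and pd.api.types.is_numeric_dtype(table[c])]
    grouped = table.groupby(by)[metrics]
    out = pd.concat(
        {"mean": grouped.mean(), "min": grouped.min(), "max": grouped.max()},
        axis=1,
    )
    out.columns = [f"{m}_{stat}" for stat, m in out.columns]
    out.insert(0, "n_jumps", grouped.size())
    mean = table[metrics].mean()
    sd = table[metrics].std(ddof=1).fillna(0.0)
    cohort = {"n_jumps": len(table)}
    for m in metrics:
        cohort[f"{m}_mean"] = mean[m]
        cohort[f"{m}_min"] = mean[m] - sd[m]
        cohort[f"{m}_max"] = mean[m] + sd[m]
    out.loc["cohort"] = pd.Series(cohort)
    return out


def render_report(cohort, out_dir, threshold: float = POWER_DENSITY_CEILING) -> dict:
    """Write figures and the cohort CSV for a fitted :class:`CohortResults`.

    Returns a dict of written paths. Output is deterministic for a fixed
    fitted cohort.
    """
    results = cohort.results
    if not results:
        raise ValueError("empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    # per-larva summary table
    summary = summarize_cohort(cohort.table)
    csv_path = os.path.join(out_dir, "cohort_summary.csv")
    summary.to_csv(csv_path, float_format="%.6g")
    paths["summary_csv"] = csv_path

    # trajectory overlay, coloured per larva
    fig, ax = plt.subplots(figsize=(6, 4))
    larvae = cohort.table["larva"].to_numpy()
    cmap = plt.get_cmap("tab20")
    for res, larva in zip(results, larvae):
        t = res.trajectory
        ax.plot(t.x * 1e3, t.y * 1e3, lw=0.8,
                color=cmap(int(larva) % 20), alpha=0.9)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("Jump trajectories (reoriented)")
    fig.tight_layout()
    paths["trajectories"] = os.path.join(out_dir, "trajectories.png")
    fig.savefig(paths["trajectories"], dpi=150)
    plt.close(fig)

    # kinematic curves of the first jump, with phase shading
    res = results[0]
    ann = res.model.annotation
    t = res.trajectory.times
    fig, axes = plt.subplots(3, 1, figsize=(6, 7), sharex=True)
    axes[0].plot(t, res.cumulative_displacement * 1e3, lw=0.8)
    axes[0].set_ylabel("displacement (mm)")
    axes[1].plot(t, res.curves.velocity, lw=0.8)
    axes[1].set_ylabel("velocity (m/s)")
    axes[2].plot(t, res.curves.acceleration, lw=0.8)
    axes[2].set_ylabel("acceleration (m/s$^2$)")
    axes[2].set_xlabel("time (s)")
    spans = [(ann.loading_start, ann.latch_start, "#dddddd"),
             (ann.latch_start, ann.launch_start, "#ffd9a0"),
             (ann.launch_start, ann.airborne_start, "#ffb0b0"),
             (ann.airborne_start, ann.landing, "#c8e6ff")]
    for ax in axes:
        for lo, hi, color in spans:
            ax.axvspan(t[lo], t[hi], color=color, alpha=0.5, lw=0)
    fig.tight_layout()
    paths["kinematics"] = os.path.join(out_dir, "kinematics.png")
    fig.savefig(paths["kinematics"], dpi=150)
    plt.close(fig)

    # power density vs muscle fraction
    sweep = cohort.sweep
    fig, ax = plt.subplots(figsize=(6, 4))
    fracs = np.array(sweep.power_density.columns, dtype=float)
    for _, row in sweep.power_density.iterrows():
        ax.plot(fracs * 100, row.to_numpy(), "o-", ms=3, lw=0.5,
                color="steelblue", alpha=0.5)
    ax.axhline(threshold, color="red", ls="--", lw=1,
               label=f"{threshold:.0f} W/kg muscle ceiling")
    ax.set_yscale("log")
    ax.set_xlabel("assumed muscle mass fraction (%)")
    ax.set_ylabel("power density (W/kg muscle)")
    ax.legend()
    fig.tight_layout()
    paths["scenarios"] = os.path.join(out_dir, "power_density_scenarios.png")
    fig.savefig(paths["scenarios"], dpi=150)
    plt.close(fig)
    return paths
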