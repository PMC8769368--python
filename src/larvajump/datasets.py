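"""Reference per-larva jump summaries for *Laemophloeus biguttatus*.

Published high-speed-video measurements of 29 jumps by 11 larvae (one row
per larva; bracketed ranges in the source are carried as ``*_min``/``*_max``
columns where the analysis needs them). All jump calculations for this
cohort use the average body mass, 1.3 mg, because individual masses could
not be resolved on the balance used. Power densities are quoted at the
microCT muscle-mass fraction of 9.78%.

Used by the worked examples, validation tests and the reproduction script;
an analysis of new data never needs it.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort", "COHORT_BODY_MASS", "COHORT_MUSCLE_FRACTION",
           "reference_cohort_means"]

#: Cohort-average body mass (kg) used for every jump calculation.
COHORT_BODY_MASS = 1.3e-6

#: Muscle mass fraction from microCT muscle volume (0.12 mm^3 x 1060 kg/m^3).
COHORT_MUSCLE_FRACTION = 0.0978

_ROWS = [
    # n_jumps, body_length_mm, loading_s, latch_ms, launch_ms, launch_dist_mm,
    # power_density (mean, min, max) at c=0.0978, v_max_ms, energy_e7_J,
    # angle_deg, distance_mm, height_mm
    (4, 6.22, 0.12, 3.6, 1.48, 1.0, 118, 44, 258, 0.39, 1.03, 106.4, 11.8, 5.9),
    (4, 5.94, 0.33, 21.1, 1.09, 1.2, 334, 0.11, 693, 0.51, 1.70, 83.7, 14.0, 13.2),
    (2, 5.46, 0.27, 2.0, 1.72, 1.1, 229, 202, 257, 0.39, 0.99, 95.0, 7.5, 8.5),
    (2, 6.32, 0.14, 3.9, 1.56, 1.3, 104, 99, 108, 0.29, 0.53, 77.5, 7.9, 3.9),
    (4, 5.53, 0.51, 3.2, 0.86, 0.9, 159, 34, 411, 0.32, 0.78, 56.0, 10.3, 4.6),
    (3, 5.86, 0.10, 1.1, 1.46, 1.3, 913, 545, 1206, 0.59, 2.26, 88.9, 13.6, 7.3),
    (1, 4.24, 0.30, 8.8, 0.63, 1.4, 24, 24, 24, 0.54, 1.90, 62.1, 11.8, 7.6),
    (1, 4.88, 0.15, 0.6, 1.56, 0.9, 767, 767, 767, 0.55, 1.99, 73.3, 8.7, 8.5),
    (3, 5.22, 0.10, 3.2, 1.77, 1.2, 121, 74, 157, 0.46, 1.38, 74.5, 11.1, 11.1),
    (3, 5.82, 0.11, 2.9, 1.77, 2.5, 642, 259, 1319, 0.72, 3.62, 95.6, 14.0, 3.6),
    (2, 5.58, 0.13, 3.0, 2.19, 2.1, 213, 119, 307, 0.63, 2.74, 58.9, 9.8, 11.2),
]

_COLUMNS = [
    "n_jumps", "body_length_mm", "loading_s", "latch_ms", "launch_ms",
    "launch_dist_mm", "power_density_mean", "power_density_min",
    "power_density_max", "v_max_ms", "energy_e7_J", "angle_deg",
    "distance_mm", "height_mm",
]

# Cohort-level means as published (jump-weighted over all 29 jumps).
_COHORT_MEANS = {
    "loading_s": 0.22, "latch_ms": 5.5, "launch_ms": 1.4,
    "launch_dist_mm": 1.3, "power_density_mean": 323.0, "v_max_ms": 0.47,
    "energy_e7_J": 1.59, "angle_deg": 79.6, "distance_mm": 11.2,
    "height_mm": 7.9, "body_length_mm": 5.55,
}


def reference_cohort() -> pd.DataFrame:
    """Per-larva reference table (11 rows), indexed by larva number."""
    df = pd.DataFrame(_ROWS, columns=_COLUMNS)
    df.index = pd.RangeIndex(1, len(df) + 1, name="larva")
    return df


def reference_cohort_means() -> pd.Series:
    """Published cohort-mean row (over all 29 jumps)."""
    return pd.Series(_COHORT_MEANS, name="cohort_mean")
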