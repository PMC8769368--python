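import numpy as np
import pytest

import larvajump as lj


@pytest.fixture(scope="session")
def default_jump():
    """One synthetic jump at the study-condition defaults (seeded)."""
    return lj.generate_trajectory(lj.SyntheticJumpTruth(seed=7))


@pytest.fixture(scope="session")
def clean_jump():
    """Noiseless, unquantised jump at v=0.5 m/s, 60 degrees."""
    truth = lj.SyntheticJumpTruth(takeoff_speed=0.5, takeoff_angle=60.0,
                                  noise_sd=0.0, pixel_scale=None, seed=0)
    return lj.generate_trajectory(truth)


@pytest.fixture(scope="session")
def rendered_jump():
    """Short noiseless jump rendered to an image stack (coarse scale to
    keep the stack small)."""
    truth = lj.SyntheticJumpTruth(takeoff_speed=0.4, takeoff_angle=65.0,
                                  loading_duration=0.01, pixel_scale=1e-4,
                                  noise_sd=0.0, seed=0)
    jump = lj.generate_trajectory(truth)
    return lj.render_frames(jump, blob_diameter=9, grid_spacing_px=50)


def fit_relative_to_takeoff(jump):
    """Parabola fit of the airborne arc with the takeoff point at the origin,
    so apex height and range compare directly to the projectile closed forms."""
    from larvajump.kinematics import airborne_points, fit_parabola

    traj = lj.reorient(jump.trajectory)
    x, y = airborne_points(traj, jump.annotation)
    return fit_parabola(x - x[0], y - y[0])


@pytest.fixture(scope="session")
def takeoff_fit():
    return fit_relative_to_takeoff
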