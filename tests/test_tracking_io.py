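"""Centroid tracking, calibration, reorientation and trajectory CSV I/O."""

import numpy as np
import pytest

import larvajump as lj
from larvajump.kinematics import airborne_points, apex_height, fit_parabola, horizontal_range
from larvajump.phases import PhaseAnnotation
from larvajump.trajectory import TrackedTrajectory


def _disk_stack(n_frames, h, w, row, col, radius=4):
    rr, cc = np.mgrid[0:h, 0:w]
    frame = np.where((rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2, 20, 230)
    return np.broadcast_to(frame.astype(np.uint8), (n_frames, h, w)).copy()


class TestTrackCentroids:
    def test_static_blob_centroid(self):
        stack = _disk_stack(5, 80, 120, row=30, col=40)
        traj = lj.track_centroids(stack, threshold=120)
        assert np.allclose(traj.x, 40.0, atol=0.5)
        assert np.allclose(traj.y, (80 - 1) - 30.0, atol=0.5)
        assert traj.units == "px"

    def test_rendered_jump_tracked_within_one_pixel(self, rendered_jump):
        truth = rendered_jump.truth
        traj = lj.track_centroids(rendered_jump.frames, threshold=120,
                                  frame_rate=truth.frame_rate)
        ox, oy = rendered_jump.render_origin_px
        x_true = rendered_jump.trajectory.x / truth.pixel_scale - ox
        y_true = rendered_jump.trajectory.y / truth.pixel_scale - oy
        assert np.abs(traj.x - x_true).max() <= 1.0
        assert np.abs(traj.y - y_true).max() <= 1.0

    def test_constant_velocity_blob_collinear(self):
        # diagonal motion, 4 px/frame; tracked centroids must be collinear
        n, h, w = 10, 100, 120
        rr, cc = np.mgrid[0:h, 0:w]
        stack = np.empty((n, h, w), dtype=np.uint8)
        for i in range(n):
            row, col = 20 + 4 * i, 30 + 4 * i
            stack[i] = np.where((rr - row) ** 2 + (cc - col) ** 2 <= 16, 20, 230)
        traj = lj.track_centroids(stack, threshold=120)
        slope, intercept = np.polyfit(traj.x, traj.y, 1)
        resid = traj.y - (slope * traj.x + intercept)
        r2 = 1 - resid.var() / traj.y.var()
        assert r2 > 0.999

    def test_all_background_stack_errors(self):
        stack = np.full((3, 20, 20), 230, dtype=np.uint8)
        with pytest.raises(ValueError, match="no foreground pixels in frame 0"):
            lj.track_centroids(stack, threshold=120)

    def test_input_validation(self):
        stack = np.full((3, 20, 20), 230, dtype=np.uint8)
        with pytest.raises(ValueError):
            lj.track_centroids(stack, threshold=300)
        with pytest.raises(ValueError):
            lj.track_centroids(np.empty((0, 5, 5), dtype=np.uint8), threshold=100)
        with pytest.raises(ValueError):
            lj.track_centroids(stack, threshold=100, polarity="sideways")


class TestRenderFrames:
    def test_blob_too_small_rejected(self, clean_jump):
        with pytest.raises(ValueError, match="blob_diameter"):
            lj.render_frames(clean_jump, blob_diameter=1)

    def test_out_of_bounds_names_frame(self, rendered_jump):
        with pytest.raises(ValueError, match="frame"):
            lj.render_frames(rendered_jump, blob_diameter=9, shape=(20, 20))


class TestCalibration:
    @pytest.mark.parametrize("px,m,expected", [(50, 0.005, 1e-4), (100, 0.005, 5e-5)])
    def test_meters_per_pixel(self, px, m, expected):
        assert lj.calibrate_scale(px, m).meters_per_pixel == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lj.calibrate_scale(0, 0.005)

    def test_apply_calibration(self):
        traj = TrackedTrajectory(times=np.arange(3) / 100.0, x=[0, 10, 20],
                                 y=[0, 5, 10], frame_rate=100.0, units="px")
        cal = lj.calibrate_scale(100, 0.005)
        metric = lj.apply_calibration(traj, cal)
        assert metric.units == "m"
        assert np.allclose(metric.x, np.array([0, 10, 20]) * 5e-5)


class TestReorient:
    def _traj(self, x, y, fps=100.0):
        return TrackedTrajectory(times=np.arange(len(x)) / fps, x=x, y=y,
                                 frame_rate=fps, units="m")

    def test_translation_preserves_distances(self):
        traj = self._traj([3e-3, 4e-3, 6e-3], [7e-3, 9e-3, 8e-3])
        out = lj.reorient(traj)
        assert out.x[0] == 0 and out.y[0] == 0
        d_in = np.hypot(np.diff(traj.x), np.diff(traj.y))
        d_out = np.hypot(np.diff(out.x), np.diff(out.y))
        assert np.allclose(d_in, d_out, atol=1e-12)

    def test_leftward_jump_reflected(self):
        out = lj.reorient(self._traj([0, -1e-3, -3e-3], [0, 1e-3, 2e-3]))
        assert out.reflected
        assert out.x[-1] - out.x[0] > 0

    def test_idempotent(self):
        once = lj.reorient(self._traj([5e-3, 1e-3, -2e-3], [1e-3, 2e-3, 3e-3]))
        twice = lj.reorient(once)
        assert np.array_equal(once.x, twice.x)
        assert np.array_equal(once.y, twice.y)
        assert once.reflected == twice.reflected

    def test_zero_net_displacement_warns(self):
        with pytest.warns(UserWarning, match="zero net"):
            lj.reorient(self._traj([0, 1e-3, 0], [0, 1e-3, 2e-3]))

    def test_ballistics_invariant_under_rigid_raw_transforms(self, clean_jump):
        """Apex and range must not depend on raw-frame placement/mirroring."""
        base = clean_jump.trajectory
        ann = clean_jump.annotation

        def pipeline(traj):
            r = lj.reorient(traj)
            x, y = airborne_points(r, ann)
            fit = fit_parabola(x - x[0], y - y[0])
            return apex_height(fit), horizontal_range(fit)

        h0, d0 = pipeline(base)
        shifted = TrackedTrajectory(times=base.times, x=-base.x + 0.01,
                                    y=base.y + 0.02, frame_rate=base.frame_rate,
                                    units="m", source="synthetic")
        h1, d1 = pipeline(shifted)
        assert h1 == pytest.approx(h0, rel=1e-9)
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestTrajectoryCsv:
    def test_round_trip_exact(self, tmp_path, default_jump):
        path = tmp_path / "traj.csv"
        traj = default_jump.trajectory
        lj.write_trajectory_csv(traj, path)
        back = lj.read_trajectory_csv(path)
        assert np.array_equal(back.x, traj.x)
        assert np.array_equal(back.y, traj.y)
        assert back.frame_rate == traj.frame_rate
        assert back.source == "imported"

    def test_duplicate_frame_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("# frame_rate_hz: 100\nframe,t_s,x,y\n"
                        "0,0.0,0,0\n1,0.01,1,1\n1,0.02,2,2\n")
        with pytest.raises(ValueError, match="duplicated frame"):
            lj.read_trajectory_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# frame_rate_hz: 100\nframe,t_s,x\n0,0.0,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            lj.read_trajectory_csv(path)

    def test_pixel_file_with_calibration_becomes_metric(self, tmp_path):
        traj = TrackedTrajectory(times=np.arange(3) / 100.0, x=[0, 10, 20],
                                 y=[0, 1, 2], frame_rate=100.0, units="px")
        path = tmp_path / "px.csv"
        lj.write_trajectory_csv(traj, path)
        cal = lj.calibrate_scale(50, 0.005)
        metric = lj.read_trajectory_csv(path, calibration=cal)
        assert metric.units == "m"
        assert np.allclose(metric.x, np.array([0, 10, 20]) * 1e-4)


def test_tracking_plus_calibration_close_to_ground_truth(rendered_jump):
    """Track -> calibrate: pointwise distance to truth within one pixel size."""
    truth = rendered_jump.truth
    traj = lj.track_centroids(rendered_jump.frames, threshold=120,
                              frame_rate=truth.frame_rate)
    cal = lj.ScaleCalibration(meters_per_pixel=truth.pixel_scale)
    metric = lj.apply_calibration(traj, cal)
    ox, oy = rendered_jump.render_origin_px
    dx = metric.x - (rendered_jump.trajectory.x - ox * truth.pixel_scale)
    dy = metric.y - (rendered_jump.trajectory.y - oy * truth.pixel_scale)
    assert np.hypot(dx, dy).max() <= truth.pixel_scale
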