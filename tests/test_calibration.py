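"""Camera projection and the two pixel-to-metre calibration models."""

import numpy as np
import pytest

from fallkin.calibration import (
    BehindCameraError,
    CalibrationMapping,
    CameraModel,
    GridSpec,
    apply_calibration,
    calibrate_from_grid,
    fit_grid_homography,
    fit_height_scale,
    image_grid,
    perturb_grid,
    project_point,
)
from fallkin.trials import Trial2D, TrialMeta


def _dlt_oracle(image_pts, world_pts):
    """Plain (unnormalized) DLT, independent of the implementation path."""
    rows = []
    for (u, v), (x, y) in zip(image_pts, world_pts):
        rows.append([u, v, 1, 0, 0, 0, -x * u, -x * v, -x])
        rows.append([0, 0, 0, u, v, 1, -y * u, -y * v, -y])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    return vt[-1].reshape(3, 3)


class TestProjection:
    def test_scene_centre_maps_to_principal_point(self, camera_90):
        px = project_point(camera_90, np.asarray(camera_90.scene_centre))
        np.testing.assert_allclose(px, camera_90.principal_point, atol=1e-9)

    def test_known_separation_follows_pinhole_formula(self, camera_90):
        # two points 0.4 m apart on the fall plane at depth d map to pixels
        # f * 0.4 / d apart
        d = camera_90.distance
        p1 = np.array([0.0, 0.0, 0.8])
        p2 = np.array([0.4, 0.0, 0.8])
        px1, px2 = project_point(camera_90, np.vstack([p1, p2]))
        sep = np.linalg.norm(px2 - px1)
        assert sep == pytest.approx(camera_90.focal_length * 0.4 / d, rel=1e-9)

    def test_out_of_plane_motion_invisible_at_90deg_to_first_order(self, camera_90):
        p = np.array([0.0, 0.0, 0.8])
        px0 = project_point(camera_90, p)
        px1 = project_point(camera_90, p + [0.0, 0.05, 0.0])
        # depth-only change: on-axis point does not move at all
        np.testing.assert_allclose(px0, px1, atol=1e-9)

    def test_point_behind_camera_rejected(self, camera_90):
        behind = camera_90.position + np.array([0.0, 1.0, 0.0])
        with pytest.raises(BehindCameraError):
            project_point(camera_90, behind)

    def test_quantization_error_bounded(self, camera_90, rng):
        pts = rng.uniform([-1, -0.2, 0.2], [1, 0.2, 1.5], size=(50, 3))
        px = project_point(camera_90, pts)
        pxq = project_point(camera_90, pts, quantize=True)
        assert np.abs(px - pxq).max() <= 0.5


class TestGridHomography:
    def test_noise_free_recovery_within_1mm(self, camera_90):
        grid = GridSpec()
        mapping = calibrate_from_grid(camera_90, grid, noise_px=0.0)
        world = mapping.pixels_to_metres(image_grid(camera_90, grid))
        err = np.linalg.norm(world - grid.nominal_plane_coords(), axis=1)
        assert err.max() < 1e-3

    def test_agrees_with_independent_dlt_oracle(self, camera_90):
        grid = GridSpec()
        px = image_grid(camera_90, grid)
        nominal = grid.nominal_plane_coords()
        mapping = fit_grid_homography(px, nominal)
        oracle = _dlt_oracle(px, nominal)
        h = np.column_stack([px, np.ones(len(px))])
        w_oracle = (h @ oracle.T)
        w_oracle = w_oracle[:, :2] / w_oracle[:, 2:3]
        np.testing.assert_allclose(
            mapping.pixels_to_metres(px), w_oracle, atol=1e-6
        )

    def test_fronto_parallel_mapping_is_similarity(self, camera_90):
        mapping = calibrate_from_grid(camera_90, GridSpec(), noise_px=0.0)
        m = mapping.matrix / mapping.matrix[2, 2]
        # perspective terms vanish and the linear part is a scaled rotation
        assert abs(m[2, 0]) < 1e-9 and abs(m[2, 1]) < 1e-9
        a = m[:2, :2]
        np.testing.assert_allclose(a.T @ a, (a[0, 0]**2 + a[0, 1]**2) * np.eye(2),
                                   atol=1e-12)

    def test_1px_noise_keeps_world_rms_under_5mm(self, camera_90):
        grid = GridSpec()
        rng = np.random.default_rng(99)
        errs = []
        clean_px = image_grid(camera_90, grid)
        for _ in range(20):
            mapping = calibrate_from_grid(camera_90, grid, noise_px=1.0, rng=rng)
            world = mapping.pixels_to_metres(clean_px)
            errs.append(np.linalg.norm(world - grid.nominal_plane_coords(), axis=1))
        assert np.sqrt(np.mean(np.concatenate(errs) ** 2)) < 5e-3

    def test_collinear_points_rejected(self):
        px = np.column_stack([np.arange(6.0), np.arange(6.0)])
        world = px * 0.01
        with pytest.raises(ValueError, match="degenerate|collinear|singular"):
            fit_grid_homography(px, world)

    def test_json_round_trip(self, camera_90):
        mapping = calibrate_from_grid(camera_90, GridSpec(), noise_px=0.0)
        back = CalibrationMapping.from_json(mapping.to_json())
        np.testing.assert_allclose(back.matrix, mapping.matrix)
        assert back.kind == "grid2d"


class TestHeightScale:
    def test_scale_from_pixel_span(self):
        mapping = fit_height_scale((100.0, 50.0), (100.0, 390.0), 1.70)
        assert mapping.scale == pytest.approx(0.005)

    def test_height_error_inflates_lengths_proportionally(self):
        m_true = fit_height_scale((0, 0), (0, 340), 1.70)
        m_err = fit_height_scale((0, 0), (0, 340), 1.80)
        assert m_err.scale / m_true.scale == pytest.approx(1.80 / 1.70)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            fit_height_scale((10.0, 10.0), (10.0, 10.0), 1.70)

    def test_line1d_agrees_with_grid2d_on_vertical_at_90deg(self, camera_90):
        # a vertical drop reconstructed by both calibrations agrees within 2%
        grid_map = calibrate_from_grid(camera_90, GridSpec(), noise_px=0.0)
        top = np.array([0.2, 0.0, 1.5])
        bottom = np.array([0.2, 0.0, 0.3])
        px = project_point(camera_90, np.vstack([top, bottom]))
        foot = project_point(camera_90, np.array([0.0, 0.0, 0.0]))
        head = project_point(camera_90, np.array([0.0, 0.0, 1.70]))
        line_map = fit_height_scale(head, foot, 1.70, horizontal_sign=-1)
        drop_grid = np.diff(grid_map.pixels_to_metres(px)[:, 1])[0]
        drop_line = np.diff(line_map.pixels_to_metres(px)[:, 1])[0]
        assert drop_line == pytest.approx(drop_grid, rel=0.02)


class TestApplyCalibration:
    def _pixel_trial(self, markers):
        meta = TrialMeta("t", "forward", "perturbation", 1.7, 0, 2, 30.0)
        return Trial2D(meta, 90.0, "pixel", markers)

    def test_identity_homography_preserves_values(self):
        mapping = CalibrationMapping(kind="grid2d", matrix=np.eye(3))
        t = self._pixel_trial({"head": np.array([[10.0, 20.0], [30.0, 40.0]])})
        out = apply_calibration(mapping, t)
        np.testing.assert_array_equal(out.markers["head"], t.markers["head"])
        assert out.unit == "metre"

    def test_scalar_scale(self):
        mapping = CalibrationMapping(
            kind="line1d", scale=0.005, origin_px=(0.0, 0.0), horizontal_sign=1
        )
        t = self._pixel_trial({"head": np.array([[0.0, 0.0], [100.0, 0.0]])})
        out = apply_calibration(mapping, t)
        assert out.markers["head"][1, 0] == pytest.approx(0.5)

    def test_metre_trial_rejected(self):
        mapping = CalibrationMapping(kind="grid2d", matrix=np.eye(3))
        meta = TrialMeta("t", "forward", "perturbation", 1.7, 0, 2, 30.0)
        t = Trial2D(meta, 90.0, "metre", {"head": np.zeros((3, 2))})
        with pytest.raises(ValueError, match="pixel"):
            apply_calibration(mapping, t)

    def test_end_to_end_inplane_reconstruction_within_2mm(self, camera_90):
        # noise-free fall-plane points -> camera -> grid calibration -> metres
        mapping = calibrate_from_grid(camera_90, GridSpec(), noise_px=0.0)
        rng = np.random.default_rng(5)
        pts = rng.uniform([-0.7, 0.0, 0.1], [0.7, 0.0, 1.5], size=(40, 3))
        px = project_point(camera_90, pts)
        world = mapping.pixels_to_metres(px)
        err = np.linalg.norm(world - pts[:, [0, 2]], axis=1)
        assert err.max() < 2e-3


class TestPerturbGrid:
    def test_zero_perturbation_is_identity(self):
        g = GridSpec()
        assert perturb_grid(g, 0.0, 0.0) == g

    @pytest.mark.parametrize("trans,rot", [(0.6, 0.0), (0.0, 50.0)])
    def test_out_of_range_rejected(self, trans, rot):
        with pytest.raises(ValueError):
            perturb_grid(GridSpec(), trans, rot)

    def test_translation_toward_camera_shrinks_reconstruction_by_depth_ratio(
        self, camera_90
    ):
        # pinhole similar triangles: grid at depth d-t makes fall-plane
        # lengths come out scaled by (d-t)/d
        t = 0.2
        d = camera_90.distance
        mapping = calibrate_from_grid(
            camera_90, perturb_grid(GridSpec(), translation=t), noise_px=0.0
        )
        p1 = np.array([0.0, 0.0, 0.8])
        p2 = np.array([0.5, 0.0, 0.8])
        px = project_point(camera_90, np.vstack([p1, p2]))
        w = mapping.pixels_to_metres(px)
        length = np.linalg.norm(w[1] - w[0])
        assert length == pytest.approx(0.5 * (d - t) / d, rel=1e-6)

    def test_rotation_sweep_increases_velocity_error(self, small_batch):
        from fallkin.pipeline import run_sweep

        rec = run_sweep(
            small_batch[:6], "grid_rotation", [0.0, 15.0, 30.0, 45.0], seed=4
        )
        by_rot = (
            rec[rec.outcome.isin(["vel_v", "vel_h"])]
            .groupby("sweep_value")["rmse"]
            .mean()
        )
        assert by_rot[15.0] < by_rot[30.0] < by_rot[45.0]
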