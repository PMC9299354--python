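"""Target geometry: zigzag construction, corner detection, rectification,
point-to-polyline distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from cervitrace import (
    CameraSpec,
    build_zigzag_pattern,
    detect_board_corners,
    estimate_rectification,
    map_to_pattern_mm,
    point_to_centerline_distance,
    render_frames,
    simulate_trajectory,
    TrajectoryScript,
)
from cervitrace.errors import (
    CornerDetectionError,
    DegenerateGeometryError,
    GeometryInfeasibleError,
    NumericDegeneracyError,
)
from cervitrace.pattern import (
    Rectification,
    load_pattern_spec,
    pattern_to_svg,
    save_pattern_spec,
)


def segment_length_sum(centerline):
    return float(np.linalg.norm(np.diff(centerline, axis=0), axis=1).sum())


class TestZigzagConstruction:
    def test_default_path_length_is_1000mm(self, pattern):
        assert pattern.path_length_mm == pytest.approx(1000.0, abs=1e-3)
        assert segment_length_sum(pattern.centerline) == pytest.approx(1000.0, abs=1e-3)

    def test_centerline_inside_board(self, pattern):
        w, h = pattern.board_size_mm
        assert (pattern.centerline[:, 0] >= 0).all()
        assert (pattern.centerline[:, 0] <= w).all()
        assert (pattern.centerline[:, 1] >= 0).all()
        assert (pattern.centerline[:, 1] <= h).all()

    def test_degenerate_zigzag_is_straight_line(self):
        p = build_zigzag_pattern(
            n_peaks=1, amplitude_mm=0.0, board_size_mm=(1100.0, 297.0)
        )
        assert p.path_length_mm == pytest.approx(1000.0)
        ys = p.centerline[:, 1]
        assert np.allclose(ys, ys[0])
        assert segment_length_sum(p.centerline) == pytest.approx(1000.0)

    def test_vertical_is_rotation_of_horizontal(self):
        ph = build_zigzag_pattern(orientation="horizontal")
        pv = build_zigzag_pattern(orientation="vertical")
        ch = np.array([210.0, 148.5])  # landscape board centre
        cv_ = np.array([148.5, 210.0])
        rel = ph.centerline - ch
        rotated = np.stack([-rel[:, 1], rel[:, 0]], axis=1) + cv_
        np.testing.assert_allclose(pv.centerline, rotated, atol=1e-9)
        assert pv.path_length_mm == pytest.approx(ph.path_length_mm)

    @pytest.mark.parametrize("start", ["TL", "TR", "BL", "BR"])
    def test_path_length_invariant_under_start_corner(self, start):
        p = build_zigzag_pattern(start_corner=start)
        assert p.path_length_mm == pytest.approx(1000.0)

    def test_infeasible_geometry_raises(self):
        # path shorter than the board span cannot zigzag across it
        with pytest.raises(GeometryInfeasibleError):
            build_zigzag_pattern(path_length_mm=300.0)
        # amplitude exceeding the per-segment length
        with pytest.raises(GeometryInfeasibleError):
            build_zigzag_pattern(amplitude_mm=500.0)

    def test_spec_roundtrip(self, pattern, tmp_path):
        path = tmp_path / "pattern.yaml"
        save_pattern_spec(pattern, path)
        again = load_pattern_spec(path)
        np.testing.assert_allclose(again.centerline, pattern.centerline, atol=1e-9)

    def test_svg_export_contains_polyline(self, pattern):
        svg = pattern_to_svg(pattern)
        assert "<polyline" in svg and "svg" in svg


class TestCornerDetection:
    def test_detects_rendered_fiducials_within_2px(self, pattern, noiseless_render):
        rendered = noiseless_render["rendered"]
        corners, conf = detect_board_corners(rendered.frames[0])
        err = np.linalg.norm(corners - rendered.corner_px, axis=1).max()
        assert err < 2.0
        assert 0.0 <= conf <= 1.0

    def test_blank_frame_raises(self):
        blank = np.full((120, 160, 3), 128, dtype=np.uint8)
        with pytest.raises(CornerDetectionError):
            detect_board_corners(blank, frame_index=3)

    def test_rotated_board_keeps_tl_tr_br_bl_order(self, pattern, small_camera):
        cam = CameraSpec(**{**small_camera.__dict__, "roll_deg": 5.0})
        script = TrajectoryScript(pattern=pattern, duration_s=1.0, dwell_s=0.0,
                                  lateral_error_sd_mm=0.0)
        track, _ = simulate_trajectory(script)
        rendered = render_frames(pattern, track, cam)
        corners, _ = detect_board_corners(rendered.frames[0])
        err = np.linalg.norm(corners - rendered.corner_px, axis=1).max()
        assert err < 2.0  # matching per-index means ordering survived the roll


class TestRectification:
    def test_identity_corners_give_identity_mapping(self, pattern):
        rect = estimate_rectification(pattern.corners_mm, pattern)
        pts = np.array([[100.0, 50.0], [210.0, 148.5], [390.0, 250.0]])
        np.testing.assert_allclose(map_to_pattern_mm(pts, rect), pts, atol=1e-9)
        assert rect.residual_px < 1e-6

    def test_known_warp_recovered(self, pattern):
        rng = np.random.default_rng(11)
        h_true = np.array([[1.2, 0.1, 30.0], [-0.05, 0.9, 60.0], [1e-4, -2e-4, 1.0]])
        inv = np.linalg.inv(h_true)  # mm -> px warp
        corners_h = np.hstack([pattern.corners_mm, np.ones((4, 1))]) @ inv.T
        corners_px = corners_h[:, :2] / corners_h[:, 2:3]
        rect = estimate_rectification(corners_px, pattern)
        w, h = pattern.board_size_mm
        pts_mm = rng.uniform([0, 0], [w, h], (100, 2))
        pts_h = np.hstack([pts_mm, np.ones((100, 1))]) @ inv.T
        pts_px = pts_h[:, :2] / pts_h[:, 2:3]
        np.testing.assert_allclose(map_to_pattern_mm(pts_px, rect), pts_mm, atol=1e-6)

    def test_roundtrip_mm_px_mm(self, pattern):
        rng = np.random.default_rng(5)
        corners_px = np.array([[80.0, 60.0], [600.0, 90.0], [640.0, 400.0], [60.0, 380.0]])
        rect = estimate_rectification(corners_px, pattern)
        w, h = pattern.board_size_mm
        pts_mm = rng.uniform([0, 0], [w, h], (1000, 2))
        back = map_to_pattern_mm(
            np.column_stack([pts_mm, np.ones(1000)]) @ rect.inverse.T[:, :2]
            / (np.column_stack([pts_mm, np.ones(1000)]) @ rect.inverse.T[:, 2:3]),
            rect,
        )
        np.testing.assert_allclose(back, pts_mm, atol=1e-6)

    def test_collinear_corners_raise(self, pattern):
        bad = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 5.0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_rectification(bad, pattern)

    def test_point_at_infinity_raises(self):
        rect = Rectification(
            matrix=np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 0, -5.0]]),
            residual_px=0.0,
            source_corners_px=np.zeros((4, 2)),
        )
        with pytest.raises(NumericDegeneracyError):
            map_to_pattern_mm(np.array([5.0, 1.0]), rect)

    def test_interior_error_under_synthetic_camera(self, pattern, noiseless_render):
        # noiseless corner detections -> < 0.5 mm interior mapping error
        rendered = noiseless_render["rendered"]
        corners, _ = detect_board_corners(rendered.frames[0])
        rect = estimate_rectification(corners, pattern)
        h = rendered.homography_mm_to_px
        rng = np.random.default_rng(3)
        w_mm, h_mm = pattern.board_size_mm
        pts_mm = rng.uniform([30, 30], [w_mm - 30, h_mm - 30], (200, 2))
        proj = np.hstack([pts_mm, np.ones((200, 1))]) @ h.T
        pts_px = proj[:, :2] / proj[:, 2:3]
        err = np.linalg.norm(map_to_pattern_mm(pts_px, rect) - pts_mm, axis=1)
        assert err.max() < 0.5


class TestCenterlineDistance:
    def test_zero_on_vertices(self, pattern):
        for v in pattern.centerline:
            assert point_to_centerline_distance(v, pattern) == pytest.approx(0.0)

    def test_perpendicular_offset_from_segment_middle(self, straight_pattern):
        mid = straight_pattern.centerline.mean(axis=0)
        q = mid + np.array([0.0, 3.0])
        assert point_to_centerline_distance(q, straight_pattern) == pytest.approx(3.0)

    def test_matches_bruteforce_resampled_oracle(self, pattern):
        # oracle: exact nearest neighbour over a 0.01 mm resampling
        step = 0.01
        line = pattern.centerline
        dense = []
        for a, b in zip(line[:-1], line[1:]):
            n = int(np.ceil(np.linalg.norm(b - a) / step))
            t = np.linspace(0, 1, n + 1)
            dense.append(a + t[:, None] * (b - a))
        tree = cKDTree(np.vstack(dense))
        rng = np.random.default_rng(17)
        w, h = pattern.board_size_mm
        queries = rng.uniform([0, 0], [w, h], (1000, 2))
        oracle, _ = tree.query(queries)
        mine = point_to_centerline_distance(queries, pattern)
        assert np.abs(mine - oracle).max() < 0.02

    @settings(derandomize=True, max_examples=60)
    @given(
        x=st.floats(-50, 470), y=st.floats(-50, 350),
        dx=st.floats(-5, 5), dy=st.floats(-5, 5),
    )
    def test_distance_is_1_lipschitz_and_nonnegative(self, x, y, dx, dy):
        p = build_zigzag_pattern()
        d1 = point_to_centerline_distance(np.array([x, y]), p)
        d2 = point_to_centerline_distance(np.array([x + dx, y + dy]), p)
        assert d1 >= 0
        assert abs(d1 - d2) <= np.hypot(dx, dy) + 1e-9
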