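"""Per-slice defect detection, bridging, depth and gap area."""

import numpy as np
import pytest

from notchmorph._geom import rotation_2d
from notchmorph.radiograph import SulcusProfile, measure_sulcus_depth
from notchmorph.slicegeom import (
    BridgedSlice,
    DefectMark,
    SliceContour,
    bridge_defect,
    detect_defect_interval,
    slice_defect_depth,
    slice_gap_area,
)

from conftest import straight_dip_contour


def rect_dip_slice(depth=2.0, step=0.5):
    pts, start, end = straight_dip_contour(depth=depth, step=step)
    return SliceContour(0.0, pts, 0.5, mark=DefectMark(start, end))


def triangle_dip_slice(apex_depth=3.0):
    left = [(x, 0.0) for x in np.arange(0.0, 12.5, 0.5)]
    right = [(x, 0.0) for x in np.arange(18.0, 30.5, 0.5)]
    pts = np.array(left + [(15.0, -apex_depth)] + right)
    return SliceContour(0.0, pts, 0.5, mark=DefectMark(len(left) - 1, len(left) + 1))


class TestDetect:
    def test_convex_arc_yields_none(self):
        th = np.radians(np.arange(0, 181, 2))
        arc = 20 * np.column_stack([np.cos(th), -np.sin(th)])
        assert detect_defect_interval(SliceContour(0.0, arc, 1.0)) is None

    def test_rectangular_dip_bounds(self):
        pts, start, end = straight_dip_contour(depth=2.0)
        contour = SliceContour(0.0, pts, 0.5)
        mark = detect_defect_interval(contour, deviation_threshold=0.3)
        assert abs(mark.start_index - start) <= 1
        assert abs(mark.end_index - end) <= 1

    def test_phantom_center_slice_matches_annotation(self, fine_phantom):
        slices, _ = fine_phantom
        s = next(s for s in slices if abs(s.x_ml_mm) < 1e-9)
        det = detect_defect_interval(s)
        step = s.native_step()
        for det_i, true_i in (
            (det.start_index, s.mark.start_index),
            (det.end_index, s.mark.end_index),
        ):
            assert np.linalg.norm(s.points[det_i] - s.points[true_i]) <= step + 1e-9

    def test_shallow_deviation_below_threshold_ignored(self):
        pts, _, _ = straight_dip_contour(depth=0.2)
        assert detect_defect_interval(SliceContour(0.0, pts, 0.5)) is None


class TestBridge:
    def test_collinear_flanks_fall_back_to_chord(self):
        s = rect_dip_slice()
        b = bridge_defect(s, s.mark)
        chord = np.linspace(b.bridge_points[0], b.bridge_points[-1], len(b.bridge_points))
        assert np.abs(b.bridge_points - chord).max() < 1e-6

    def test_circular_flanks_reconstruct_circle(self, fine_phantom):
        slices, _ = fine_phantom
        s = next(s for s in slices if abs(s.x_ml_mm) < 1e-9)
        b = bridge_defect(s, s.mark)
        radius = np.linalg.norm(b.bridge_points, axis=1)
        assert np.abs(radius - 20.0).max() < 0.1

    def test_bridge_shares_mark_endpoints(self):
        s = rect_dip_slice()
        b = bridge_defect(s, s.mark)
        np.testing.assert_array_equal(b.bridge_points[0], s.points[s.mark.start_index])
        np.testing.assert_array_equal(b.bridge_points[-1], s.points[s.mark.end_index])

    def test_insufficient_flank_raises_with_slice_position(self):
        pts = np.array([(0, 0), (1, 0), (2, -1), (3, -1), (4, 0), (5, 0)], dtype=float)
        contour = SliceContour(7.25, pts, 0.5)
        with pytest.raises(ValueError, match="7.25"):
            bridge_defect(contour, DefectMark(0, 4))


class TestDepthAndArea:
    def test_rectangular_dip_depth(self):
        s = rect_dip_slice(depth=2.0)
        assert slice_defect_depth(bridge_defect(s, s.mark)) == pytest.approx(2.0)

    def test_triangular_dip_depth(self):
        s = triangle_dip_slice(apex_depth=3.0)
        assert slice_defect_depth(bridge_defect(s, s.mark)) == pytest.approx(3.0)

    def test_phantom_center_depth(self, fine_phantom):
        slices, _ = fine_phantom
        s = next(s for s in slices if abs(s.x_ml_mm) < 1e-9)
        d = slice_defect_depth(bridge_defect(s, s.mark))
        assert d == pytest.approx(3.0, abs=0.1)

    def test_rectangular_gap_area(self):
        s = rect_dip_slice(depth=2.0)  # width 6 x depth 2
        assert slice_gap_area(bridge_defect(s, s.mark)) == pytest.approx(12.0)

    def test_triangular_gap_area(self):
        s = triangle_dip_slice(apex_depth=3.0)  # base 6, height 3
        assert slice_gap_area(bridge_defect(s, s.mark)) == pytest.approx(9.0)

    def test_gap_area_matches_shoelace(self, fine_phantom):
        slices, _ = fine_phantom
        s = next(s for s in slices if abs(s.x_ml_mm) < 1e-9)
        b = bridge_defect(s, s.mark)
        ring = np.vstack([b.bridge_points, b.depressed_points[::-1]])
        x, y = ring[:, 0], ring[:, 1]
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert slice_gap_area(b) == pytest.approx(shoelace, rel=1e-6)

    def test_degenerate_gap_has_zero_area(self):
        pts = np.array([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0), (5, 0)], dtype=float)
        s = SliceContour(0.0, pts, 0.5, mark=DefectMark(2, 3))
        b = bridge_defect(s, s.mark)
        assert slice_gap_area(b) == pytest.approx(0.0, abs=1e-9)

    def test_agreement_with_radiograph_on_straight_flanks(self):
        # With collinear flanks the bridge is the tangential chord, so the
        # slice depth equals the radiographic sulcus depth.
        s = rect_dip_slice(depth=2.0)
        slice_depth = slice_defect_depth(bridge_defect(s, s.mark))
        xray_depth = measure_sulcus_depth(SulcusProfile(s.points)).depth_mm
        assert slice_depth == pytest.approx(xray_depth, abs=1e-9)

    @pytest.mark.parametrize("angle", [0.3, 1.2, -2.0])
    def test_rigid_motion_invariance(self, angle):
        s = rect_dip_slice(depth=2.0)
        ref_b = bridge_defect(s, s.mark)
        rot = rotation_2d(angle)
        moved = SliceContour(0.0, s.points @ rot.T + [5.0, -3.0], 0.5, mark=s.mark)
        b = bridge_defect(moved, moved.mark)
        assert slice_defect_depth(b) == pytest.approx(slice_defect_depth(ref_b), rel=1e-9)
        assert slice_gap_area(b) == pytest.approx(slice_gap_area(ref_b), rel=1e-9)

    def test_nested_dips_are_monotone(self):
        shallow = rect_dip_slice(depth=1.0)
        deep = rect_dip_slice(depth=2.5)
        b1, b2 = bridge_defect(shallow, shallow.mark), bridge_defect(deep, deep.mark)
        assert slice_defect_depth(b2) > slice_defect_depth(b1)
        assert slice_gap_area(b2) > slice_gap_area(b1)


def test_contour_validation():
    with pytest.raises(ValueError):
        SliceContour(0.0, np.array([(0, 0), (1, 0), (2, 0)], dtype=float), 0.5)  # < 4 pts
    with pytest.raises(ValueError):
        SliceContour(0.0, np.array([(0, 0), (0, 0), (1, 0), (2, 0)], dtype=float), 0.5)
    with pytest.raises(ValueError):
        DefectMark(5, 5)
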