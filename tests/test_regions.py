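"""Six-segment partition: plane construction, tiling and localization."""

import numpy as np
import pytest

from notchmorph.morphometry3d import bridge_marked_slices, total_surface_area, defect_metrics
from notchmorph.phantom import PhantomSpec, generate_phantom
from notchmorph.regions import (
    REGION_LABELS,
    Landmarks,
    SegmentMetrics,
    assign_regions,
    build_partition,
    classify_primary_location,
)
from notchmorph.slicegeom import SliceContour


def dummy_slices(x_positions=(0.0, 30.0)):
    line = np.column_stack([np.linspace(0, 10, 11), np.zeros(11)])
    return [SliceContour(x, line, 1.0) for x in x_positions]


def axis_landmarks(notch_y=40.0):
    return Landmarks(
        trochlear_notch_point=np.array([15.0, notch_y, 0.0]),
        posterior_point_medial=np.array([0.0, 0.0, 0.0]),
        posterior_point_lateral=np.array([30.0, 0.0, 0.0]),
        shaft_axis_direction=np.array([0.0, 0.0, 1.0]),
    )


class TestBuildPartition:
    def test_sixty_percent_plane_in_axis_aligned_fixture(self):
        # Notch at y = 40, posterior points at y = 0: plane 2 must sit at
        # y = 16 = 40 - 0.6 * 40.
        part = build_partition(dummy_slices(), axis_landmarks())
        np.testing.assert_allclose(np.abs(part.normal), [0, 1, 0], atol=1e-12)
        assert part.plane2_offset == pytest.approx(-24.0)
        assert part.band(np.array([[5.0, 16.1, 0.0]]))[0] == "C"
        assert part.band(np.array([[5.0, 15.9, 0.0]]))[0] == "P"
        assert part.band(np.array([[5.0, 40.1, 0.0]]))[0] == "A"

    def test_ml_split_at_half_extent(self):
        part = build_partition(dummy_slices((0.0, 10.0, 30.0)), axis_landmarks())
        assert part.ml_split_mm == pytest.approx(15.0)
        assert part.side(np.array([14.9]))[0] == "I"
        assert part.side(np.array([15.1]))[0] == "E"

    def test_degenerate_landmarks_rejected(self):
        bad = Landmarks(
            trochlear_notch_point=np.array([0.0, 40.0, 0.0]),
            posterior_point_medial=np.array([0.0, 0.0, 0.0]),
            posterior_point_lateral=np.array([0.0, 0.0, 10.0]),
            shaft_axis_direction=np.array([0.0, 0.0, 1.0]),  # parallel to posterior vector
        )
        with pytest.raises(ValueError, match="degenerate"):
            build_partition(dummy_slices(), bad)


class TestAssignRegions:
    def test_tiling_is_exact(self, ce_phantom):
        slices, truth = ce_phantom
        part = build_partition(slices, truth.landmarks)
        bridged = bridge_marked_slices(slices)
        segs = assign_regions(part, slices, bridged)
        total = total_surface_area(slices)
        dm = defect_metrics(bridged, total)
        assert sum(s.region_surface_cm2 for s in segs) == pytest.approx(
            total.total_area_cm2, rel=1e-9
        )
        assert sum(s.affected_area_cm2 for s in segs) == pytest.approx(
            dm.primary_area_cm2, rel=1e-9
        )
        assert sum(s.concave_area_cm2 for s in segs) == pytest.approx(
            dm.concave_area_cm2, rel=1e-9
        )
        assert sum(s.volume_mm3 for s in segs) == pytest.approx(dm.volume_mm3, rel=1e-9)

    def test_octant_aimed_defect_lands_in_ce(self, ce_phantom):
        slices, truth = ce_phantom
        part = build_partition(slices, truth.landmarks)
        segs = assign_regions(part, slices, bridge_marked_slices(slices))
        by = {s.region: s for s in segs}
        assert by["CE"].affected_area_cm2 * 100 == pytest.approx(
            truth.primary_area_mm2, rel=0.05
        )
        for lab in ("AI", "AE", "CI", "PI", "PE"):
            assert by[lab].affected_area_cm2 == pytest.approx(0.0, abs=1e-6)
        assert classify_primary_location(segs) == "CE"

    def test_no_defect_yields_zero_rows_and_no_location(self):
        slices, truth = generate_phantom(
            PhantomSpec(indent_depth_mm=0.0, in_plane_step_mm=0.4)
        )
        part = build_partition(slices, truth.landmarks)
        segs = assign_regions(part, slices, [])
        assert all(s.affected_area_cm2 == 0 and s.volume_mm3 == 0 for s in segs)
        assert classify_primary_location(segs) is None

    def test_rotation_about_ml_axis_preserves_assignment(self, ce_phantom):
        # Rotating every slice in-plane (and the landmarks with them) is a
        # rigid motion that keeps the sagittal stack valid.
        slices, truth = ce_phantom
        ang = 0.6
        c, s_ = np.cos(ang), np.sin(ang)
        R2 = np.array([[c, -s_], [s_, c]])
        R3 = np.array([[1, 0, 0], [0, c, -s_], [0, s_, c]])
        moved = [
            SliceContour(s.x_ml_mm, s.points @ R2.T, s.slice_spacing_mm, mark=s.mark)
            for s in slices
        ]
        lm = truth.landmarks
        moved_lm = Landmarks(
            trochlear_notch_point=R3 @ lm.trochlear_notch_point,
            posterior_point_medial=R3 @ lm.posterior_point_medial,
            posterior_point_lateral=R3 @ lm.posterior_point_lateral,
            shaft_axis_direction=R3 @ lm.shaft_axis_direction,
        )
        ref = assign_regions(
            build_partition(slices, lm), slices, bridge_marked_slices(slices)
        )
        got = assign_regions(
            build_partition(moved, moved_lm), moved, bridge_marked_slices(moved)
        )
        for a, b in zip(ref, got):
            assert a.region == b.region
            assert b.region_surface_cm2 == pytest.approx(a.region_surface_cm2, rel=1e-6)
            assert b.affected_area_cm2 == pytest.approx(a.affected_area_cm2, abs=1e-6)
            assert b.volume_mm3 == pytest.approx(a.volume_mm3, rel=1e-6, abs=1e-6)

    def test_moving_defect_across_split_flips_side_once(self):
        labels = []
        for ux in (-0.35, -0.15, 0.15, 0.35):
            u = np.array([ux, 0.25, -0.9])
            spec = PhantomSpec(
                indent_direction=tuple(u / np.linalg.norm(u)),
                slice_spacing_mm=1.0,
                in_plane_step_mm=0.4,
            )
            slices, truth = generate_phantom(spec)
            part = build_partition(slices, truth.landmarks)
            segs = assign_regions(part, slices, bridge_marked_slices(slices))
            labels.append(classify_primary_location(segs)[1])
        assert labels == ["I", "I", "E", "E"]


class TestClassifyPrimaryLocation:
    @staticmethod
    def segs(**affected):
        return [
            SegmentMetrics(lab, 5.0, 0, 0, 0, affected.get(lab, 0.0), 0, 0, 0)
            for lab in REGION_LABELS
        ]

    def test_single_affected_region_wins(self):
        assert classify_primary_location(self.segs(CI=1.0)) == "CI"

    def test_exact_tie_prefers_ce(self):
        assert classify_primary_location(self.segs(CE=1.0, CI=1.0)) == "CE"

    def test_all_zero_returns_none(self):
        assert classify_primary_location(self.segs()) is None
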