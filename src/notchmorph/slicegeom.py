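"""Per-slice defect geometry on sagittal subchondral-bone contours.

A knee is represented as a stack of sagittal slices; in each slice the
subchondral bone surface is an open polyline in the (anterior-posterior,
distal-proximal) plane.  Where an impaction fracture depresses the surface,
the affected vertex interval is marked and the gap is bridged with a contour
approximating the bone surface under normal anatomical conditions.  The
bridged slice yields the per-slice defect depth (deviation of the depressed
curve from the bridge) and gap cross-section area (the integrand of the
defect volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_interp_spline
from shapely.geometry import LineString, Point, Polygon

from ._geom import as_points, cross2, hull_concavities

__all__ = [
    "SliceContour",
    "DefectMark",
    "BridgedSlice",
    "detect_defect_interval",
    "bridge_defect",
    "slice_defect_depth",
    "slice_gap_area",
]


@dataclass(frozen=True)
class DefectMark:
    """Inclusive vertex interval bounding the depressed portion of a contour.

    The endpoints sit on the intact surface; strictly interior vertices are
    the depressed ones.
    """

    start_index: int
    end_index: int

    def __post_init__(self):
        if self.start_index < 0 or self.end_index <= self.start_index:
            raise ValueError(
                f"invalid defect mark [{self.start_index}, {self.end_index}]"
            )


@dataclass(frozen=True)
class SliceContour:
    """One sagittal segmentation: ordered open polyline at a known ML position.

    Points are (y, z) = (posterior→anterior, distal→proximal) coordinates in
    mm, ordered along arc length; ``x_ml_mm`` is the slice position on the
    medial→lateral axis and ``slice_spacing_mm`` the acquisition spacing.  An
    optional expert ``mark`` flags the depressed interval.
    """

    x_ml_mm: float
    points: np.ndarray
    slice_spacing_mm: float
    mark: DefectMark | None = field(default=None)

    def __post_init__(self):
        pts = as_points(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 4:
            raise ValueError(
                f"slice at x={self.x_ml_mm}: need >= 4 contour points, got {len(pts)}"
            )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError(
                f"slice at x={self.x_ml_mm}: consecutive points must be distinct"
            )
        if self.slice_spacing_mm <= 0:
            raise ValueError("slice_spacing_mm must be positive")
        if self.mark is not None and self.mark.end_index >= len(pts):
            raise ValueError(
                f"slice at x={self.x_ml_mm}: mark exceeds contour length"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    def native_step(self) -> float:
        """Median in-plane sampling step of the contour."""
        return float(np.median(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def with_mark(self, mark: DefectMark | None) -> "SliceContour":
        return replace(self, mark=mark)


@dataclass(frozen=True)
class BridgedSlice:
    """A marked slice with its gap bridged by a reconstructed healthy curve."""

    contour: SliceContour
    mark: DefectMark
    bridge_points: np.ndarray
    depressed_points: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bridge_points", as_points(self.bridge_points))
        object.__setattr__(self, "depressed_points", as_points(self.depressed_points))
        for name, curve in (("bridge", self.bridge_points), ("depressed", self.depressed_points)):
            for end, idx in (("start", self.mark.start_index), ("end", self.mark.end_index)):
                ref = self.contour.points[idx]
                pt = curve[0] if end == "start" else curve[-1]
                if not np.allclose(pt, ref, atol=1e-9):
                    raise ValueError(
                        f"{name} curve must share the contour vertex at its {end}"
                    )

    @property
    def x_ml_mm(self) -> float:
        return self.contour.x_ml_mm


def detect_defect_interval(
    contour: SliceContour, deviation_threshold: float = 0.3, bone_side: str = "right"
) -> DefectMark | None:
    """Locate the depressed interval of a contour, or ``None`` if intact.

    Automated stand-in for manual marking: the deepest convex-hull concavity
    whose perpendicular deviation exceeds ``deviation_threshold`` (mm) is
    returned, extended outward to the hull-touching vertices.  The default
    threshold sits below the finest clinical in-plane resolution so that
    sampling jitter does not trigger false marks.  ``bone_side`` declares on
    which side of the traversal direction the bone lies (an
    anterior→distal→posterior trace has it on the right).
    """
    best = None
    for conc in hull_concavities(contour.points, bone_side=bone_side):
        if conc.depth > deviation_threshold and (best is None or conc.depth > best.depth):
            best = conc
    if best is None:
        return None
    return DefectMark(best.start, best.end)


def _flank_indices(contour: SliceContour, mark: DefectMark, n_flank: int):
    left = np.arange(max(0, mark.start_index - n_flank + 1), mark.start_index + 1)
    right = np.arange(mark.end_index, min(contour.n_points, mark.end_index + n_flank))
    if len(left) < 2 or len(right) < 2:
        raise ValueError(
            f"slice at x={contour.x_ml_mm}: fewer than 2 flank vertices "
            f"on one side of the mark [{mark.start_index}, {mark.end_index}]"
        )
    return left, right


def bridge_defect(
    contour: SliceContour,
    mark: DefectMark,
    n_flank: int = 5,
    collinear_tol: float = 1e-6,
) -> BridgedSlice:
    """Bridge the marked gap with a curve approximating the intact surface.

    A cubic interpolating spline, parameterized by cumulative chord length, is
    fitted through up to ``n_flank`` contour vertices on each side of the mark
    and evaluated across the gap at the contour's native point density.  When
    the flank vertices are collinear within ``collinear_tol`` (mm) the bridge
    falls back to the straight chord.
    """
    left, right = _flank_indices(contour, mark, n_flank)
    p_start = contour.points[mark.start_index]
    p_end = contour.points[mark.end_index]
    chord = float(np.linalg.norm(p_end - p_start))
    n_gap = max(2, int(round(chord / max(contour.native_step(), 1e-12))) + 1)

    flank_pts = np.vstack([contour.points[left], contour.points[right]])
    # Deviation of all flank points from the line through the two gap endpoints.
    e = p_end - p_start
    if chord > 0:
        dev = np.abs(cross2(e, flank_pts - p_start)) / chord
        collinear = bool(np.max(dev) < collinear_tol)
    else:
        collinear = True

    if collinear:
        s = np.linspace(0.0, 1.0, n_gap)
        bridge = p_start[None, :] + s[:, None] * (p_end - p_start)[None, :]
    else:
        # Chord-length parameter; the gap itself contributes its straight chord.
        t = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(flank_pts, axis=0), axis=1))])
        k = min(3, len(flank_pts) - 1)
        spline = make_interp_spline(t, flank_pts, k=k, axis=0)
        t_lo = t[len(left) - 1]
        t_hi = t[len(left)]
        bridge = np.asarray(spline(np.linspace(t_lo, t_hi, n_gap)))
        bridge[0] = p_start  # interpolation is exact; pin endpoints bitwise
        bridge[-1] = p_end

    depressed = contour.points[mark.start_index : mark.end_index + 1]
    return BridgedSlice(contour, mark, bridge, depressed)


def slice_defect_depth(bridged: BridgedSlice) -> float:
    """Maximum distance of any depressed vertex from the bridge polyline (mm)."""
    line = LineString(bridged.bridge_points)
    return max(line.distance(Point(p)) for p in bridged.depressed_points)


def slice_gap_area(bridged: BridgedSlice) -> float:
    """Planar area (mm²) enclosed between the bridge and the depressed curve."""
    ring = np.vstack([bridged.bridge_points, bridged.depressed_points[::-1]])
    # Collapse consecutive duplicates; a fully degenerate ring has zero area.
    keep = np.ones(len(ring), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ring, axis=0), axis=1) > 1e-12
    ring = ring[keep]
    if len(ring) < 3:
        return 0.0
    poly = Polygon(ring)
    if not poly.is_valid:
        if poly.area < 1e-9:
            return 0.0
        raise ValueError(
            f"slice at x={bridged.x_ml_mm}: bridge and depressed curves form a "
            "self-intersecting polygon"
        )
    return float(poly.area)
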