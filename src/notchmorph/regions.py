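"""Six-segment regional partition of the lateral condyle surface.

Two parallel planes divide the surface antero-posteriorly: the first is
spanned by the femoral-shaft axis and the vector connecting the most
posterior points of the two condyles, passing through the trochlear notch
(separating the trochlea from the condyle proper); the second sits at 60 % of
the notch→posterior distance, separating the central weight-bearing segment
from the posterior segment.  A medio-lateral split at 50 % of the segmented
surface's extent divides each band into an internal (medial) and external
(lateral) half, yielding the segments AI, AE, CI, CE, PI, PE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon

from .morphometry3d import (
    CondyleMetrics,
    DefectMetrics,
    convert_mm2_to_cm2,
    defect_metrics,
    reconstruct_surface,
    _slab_volume,
    _strip_mesh,
)
from .slicegeom import BridgedSlice, SliceContour, slice_gap_area

__all__ = [
    "REGION_LABELS",
    "TIE_ORDER",
    "Landmarks",
    "RegionPartition",
    "SegmentMetrics",
    "build_partition",
    "assign_regions",
    "classify_primary_location",
]

#: Canonical output order of the six segments.
REGION_LABELS = ("AI", "AE", "CI", "CE", "PI", "PE")
#: Tie-break preference when calling the primary defect location.
TIE_ORDER = ("CE", "CI", "AE", "AI", "PE", "PI")

CENTRAL_FRACTION = 0.6  # plane2 position along the notch→posterior distance
ML_SPLIT_FRACTION = 0.5


@dataclass(frozen=True)
class Landmarks:
    """Anatomical landmarks anchoring the regional partition (3D mm)."""

    trochlear_notch_point: np.ndarray
    posterior_point_medial: np.ndarray
    posterior_point_lateral: np.ndarray
    shaft_axis_direction: np.ndarray

    def __post_init__(self):
        for name in (
            "trochlear_notch_point",
            "posterior_point_medial",
            "posterior_point_lateral",
            "shaft_axis_direction",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        norm = np.linalg.norm(self.shaft_axis_direction)
        if norm < 1e-9:
            raise ValueError("shaft axis direction is degenerate")
        object.__setattr__(
            self, "shaft_axis_direction", self.shaft_axis_direction / norm
        )


@dataclass(frozen=True)
class RegionPartition:
    """The two parallel AP planes plus the medio-lateral split coordinate.

    ``normal`` points anteriorly; signed distances are measured from the
    trochlear-notch plane (plane 1, offset 0) with plane 2 at the negative
    offset ``plane2_offset``.
    """

    origin: np.ndarray          # trochlear notch (on plane 1)
    normal: np.ndarray          # unit, oriented anterior
    plane2_offset: float        # signed distance of plane 2 (< 0)
    ml_split_mm: float
    labels: tuple = field(default=REGION_LABELS)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.normal

    def band(self, points: np.ndarray) -> np.ndarray:
        """'A' (trochlea), 'C' (central/weight-bearing) or 'P' per point."""
        d = self.signed_distance(points)
        out = np.where(d > 0, "A", np.where(d > self.plane2_offset, "C", "P"))
        return out

    def side(self, x_ml: np.ndarray) -> np.ndarray:
        """'I' (internal/medial) or 'E' (external/lateral) per ML coordinate."""
        return np.where(np.asarray(x_ml) < self.ml_split_mm, "I", "E")

    def label(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return np.char.add(self.band(pts), self.side(pts[:, 0]))


@dataclass(frozen=True)
class SegmentMetrics:
    """Per-segment surface and defect quantities (one row of the region table)."""

    region: str
    region_surface_cm2: float
    defect_length_mm: float
    defect_width_mm: float
    defect_depth_mm: float
    affected_area_cm2: float
    percent_of_region: float
    concave_area_cm2: float
    volume_mm3: float

    FIELDS = (
        "region_surface_cm2",
        "defect_length_mm",
        "defect_width_mm",
        "defect_depth_mm",
        "affected_area_cm2",
        "percent_of_region",
        "concave_area_cm2",
        "volume_mm3",
    )

    @classmethod
    def zeros(cls, region: str, region_surface_cm2: float = 0.0) -> "SegmentMetrics":
        return cls(region, region_surface_cm2, 0, 0, 0, 0, 0, 0, 0)


def build_partition(slices: list[SliceContour], landmarks: Landmarks) -> RegionPartition:
    """Construct the six-segment partition from landmarks and the slice stack.

    Plane 1 is spanned by the shaft axis and the medial→lateral
    posterior-points vector through the trochlear notch; plane 2 is parallel,
    offset 60 % of the signed notch→posterior distance; the medio-lateral
    split is the midpoint of the slices' position range.
    """
    if len(slices) < 2:
        raise ValueError("need at least 2 slices to build a partition")
    m = landmarks.posterior_point_lateral - landmarks.posterior_point_medial
    normal = np.cross(landmarks.shaft_axis_direction, m)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise ValueError(
            "degenerate landmarks: shaft axis is parallel to the posterior-points vector"
        )
    normal = normal / norm
    post_mid = 0.5 * (landmarks.posterior_point_medial + landmarks.posterior_point_lateral)
    s_post = float(normal @ (post_mid - landmarks.trochlear_notch_point))
    if abs(s_post) < 1e-9:
        raise ValueError("degenerate landmarks: posterior points lie on the notch plane")
    if s_post > 0:  # orient the normal anteriorly
        normal = -normal
        s_post = -s_post
    xs = np.array([s.x_ml_mm for s in slices])
    ml_split = float(
        xs.min() + ML_SPLIT_FRACTION * (xs.max() - xs.min())
    )
    if not xs.min() < ml_split < xs.max():
        raise ValueError("medio-lateral split must fall strictly inside the slice range")
    return RegionPartition(
        origin=np.asarray(landmarks.trochlear_notch_point, dtype=float),
        normal=normal,
        plane2_offset=CENTRAL_FRACTION * s_post,
        ml_split_mm=ml_split,
    )


def _mesh_area_by_region(mesh, partition: RegionPartition) -> dict[str, float]:
    centroids = mesh.triangles_center
    labels = partition.label(centroids)
    areas = mesh.area_faces
    out = {lab: 0.0 for lab in REGION_LABELS}
    for lab in REGION_LABELS:
        out[lab] = float(areas[labels == lab].sum())
    return out


def _clip_gap_polygon(b: BridgedSlice, partition: RegionPartition) -> dict[str, float]:
    """Split one slice's gap cross-section area across the three AP bands."""
    ring = np.vstack([b.bridge_points, b.depressed_points[::-1]])
    keep = np.ones(len(ring), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ring, axis=0), axis=1) > 1e-12
    poly = Polygon(ring[keep])
    if not poly.is_valid or poly.area <= 0:
        return {"A": 0.0, "C": 0.0, "P": 0.0}
    # Signed plane distance restricted to this slice plane is affine in (y, z):
    # d(y, z) = n_x * x0 + n_y*y + n_z*z - n . origin
    n = partition.normal
    c0 = float(n[0] * b.x_ml_mm - n @ partition.origin)
    pts = np.array(poly.exterior.coords)
    d = c0 + pts[:, 0] * n[1] + pts[:, 1] * n[2]
    out = {}
    for band, lo, hi in (
        ("A", 0.0, np.inf),
        ("C", partition.plane2_offset, 0.0),
        ("P", -np.inf, partition.plane2_offset),
    ):
        out[band] = _halfplane_band_area(poly, n[1], n[2], c0, lo, hi)
    return out


def _halfplane_band_area(poly: Polygon, ny: float, nz: float, c0: float, lo: float, hi: float) -> float:
    """Area of poly within lo < c0 + ny*y + nz*z <= hi, by half-plane clipping."""
    clipped = poly
    for bound, keep_above in ((lo, True), (hi, False)):
        if not np.isfinite(bound):
            continue
        clipped = _clip_halfplane(clipped, ny, nz, c0 - bound, keep_above)
        if clipped.is_empty:
            return 0.0
    return float(clipped.area)


def _clip_halfplane(poly, ny, nz, c, keep_above):
    """Intersect poly with {ny*y + nz*z + c >= 0} (or <= 0)."""
    if poly.is_empty:
        return poly
    minx, miny, maxx, maxy = poly.bounds
    span = max(maxx - minx, maxy - miny, 1.0) * 4
    # Build a large rectangle on the kept side of the line ny*y + nz*z + c = 0.
    norm = float(np.hypot(ny, nz))
    nvec = np.array([ny, nz]) / norm
    if not keep_above:
        nvec = -nvec
        c = -c
    # A point on the line nearest the polygon centroid:
    cen = np.array([poly.centroid.x, poly.centroid.y])
    dist = (nvec @ cen) + c / norm
    foot = cen - dist * nvec
    tvec = np.array([-nvec[1], nvec[0]])
    rect = Polygon(
        [
            foot - span * tvec,
            foot + span * tvec,
            foot + span * tvec + 2 * span * nvec,
            foot - span * tvec + 2 * span * nvec,
        ]
    )
    return poly.intersection(rect)


def assign_regions(
    partition: RegionPartition,
    slices: list[SliceContour],
    bridged: list[BridgedSlice],
    k: int = 200,
) -> list[SegmentMetrics]:
    """Attribute surface and defect quantities to the six segments.

    Surface triangles (whole condyle, bridged primary surface, depressed
    concave surface) are assigned by centroid; per-slice gap areas are split
    exactly at the two plane traces for the segment volumes, so segment sums
    reproduce the totals.
    """
    total_mesh = reconstruct_surface(slices, k=k, use_marks=True)
    region_surface = _mesh_area_by_region(total_mesh, partition)

    bridged = sorted((b for b in bridged if slice_gap_area(b) > 0), key=lambda b: b.x_ml_mm)
    affected = {lab: 0.0 for lab in REGION_LABELS}
    concave = {lab: 0.0 for lab in REGION_LABELS}
    volume = {lab: 0.0 for lab in REGION_LABELS}
    depth = {lab: 0.0 for lab in REGION_LABELS}
    length = {lab: 0.0 for lab in REGION_LABELS}
    slices_hit: dict[str, list[float]] = {lab: [] for lab in REGION_LABELS}

    if len(bridged) >= 2:
        x = np.array([b.x_ml_mm for b in bridged])
        primary_mesh = _strip_mesh(x, [b.bridge_points for b in bridged], k)
        concave_mesh = _strip_mesh(x, [b.depressed_points for b in bridged], k)
        affected.update(_mesh_area_by_region(primary_mesh, partition))
        concave.update(_mesh_area_by_region(concave_mesh, partition))

    if bridged:
        spacing = float(np.mean([b.contour.slice_spacing_mm for b in bridged]))
        xs = np.array([b.x_ml_mm for b in bridged])
        band_areas = {band: np.zeros(len(bridged)) for band in "ACP"}
        for i, b in enumerate(bridged):
            split_areas = _clip_gap_polygon(b, partition)
            for band in "ACP":
                band_areas[band][i] = split_areas[band]
        for band in "ACP":
            for side in "IE":
                lab = band + side
                mask = np.array([partition.side([bx])[0] == side for bx in xs])
                a = np.where(mask, band_areas[band], 0.0)
                volume[lab] = _slab_volume(xs, a, spacing)
        # Depth / AP length / slab width per segment from depressed vertices.
        from shapely.geometry import Point

        for b in bridged:
            side = partition.side([b.x_ml_mm])[0]
            pts3 = np.column_stack(
                [np.full(len(b.depressed_points), b.x_ml_mm), b.depressed_points]
            )
            labs = partition.label(pts3)
            line = LineString(b.bridge_points)
            for lab in set(labs.tolist()):
                sel = b.depressed_points[labs == lab]
                d = max(line.distance(Point(p)) for p in sel)
                depth[lab] = max(depth[lab], float(d))
                length[lab] = max(length[lab], float(np.ptp(sel[:, 0])))
                if slice_gap_area(b) > 0:
                    slices_hit[lab].append(b.x_ml_mm)
        width = {
            lab: (max(v) - min(v) + spacing if v else 0.0)
            for lab, v in slices_hit.items()
        }
    else:
        width = {lab: 0.0 for lab in REGION_LABELS}

    out = []
    for lab in REGION_LABELS:
        surf_cm2 = convert_mm2_to_cm2(region_surface[lab])
        aff_cm2 = convert_mm2_to_cm2(affected[lab])
        out.append(
            SegmentMetrics(
                region=lab,
                region_surface_cm2=surf_cm2,
                defect_length_mm=length[lab],
                defect_width_mm=width.get(lab, 0.0),
                defect_depth_mm=depth[lab],
                affected_area_cm2=aff_cm2,
                percent_of_region=(100.0 * aff_cm2 / surf_cm2 if surf_cm2 > 0 else 0.0),
                concave_area_cm2=convert_mm2_to_cm2(concave[lab]),
                volume_mm3=volume[lab],
            )
        )
    return out


def classify_primary_location(segments: list[SegmentMetrics]) -> str | None:
    """Label of the segment carrying the largest primary (affected) area.

    Ties are broken in the fixed order CE, CI, AE, AI, PE, PI; returns
    ``None`` when no segment is affected.
    """
    by_label = {s.region: s for s in segments}
    best = None
    for lab in TIE_ORDER:
        s = by_label.get(lab)
        if s is None or s.affected_area_cm2 <= 0:
            continue
        if best is None or s.affected_area_cm2 > by_label[best].affected_area_cm2:
            best = lab
    return best
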