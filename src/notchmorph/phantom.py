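"""Synthetic condyle phantoms with closed-form ground truth.

The model condyle is a sphere of radius R; the segmented subchondral zone is
the band |x| <= ml_extent of its surface, sampled as near-closed sagittal
circle contours (one small seam at the anterior-proximal position, where the
bone would continue into the shaft).  An impaction defect is realized by an
indenting sphere of radius r whose center sits at distance d = R + r − t from
the condyle center, so the deepest penetration is exactly t; surface points
inside the indenting sphere are projected onto it within their slice plane.
Every reported defect quantity then has a closed form: the primary (bridged)
area is the spherical cap cut from the condyle sphere, the concave area the
cap on the indenting sphere, and the volume the sphere–sphere intersection
lens.

Coordinate convention: x = medial→lateral, y = posterior→anterior,
z = distal→proximal; sagittal slices are planes of constant x; lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import Landmarks
from .slicegeom import DefectMark, SliceContour

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "analytic_lens_metrics",
    "analytic_zone_area",
    "generate_phantom",
    "sulcus_profile",
    "clinical_spec",
]

# Angular position of the contour seam / trochlear-notch stand-in, measured in
# the (y, z) plane from the +y (anterior) axis toward +z (proximal).
SEAM_ANGLE = np.pi / 4


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric condyle + indentation defect and its sampling geometry.

    ``condyle_radius_mm`` (R) and ``indent_radius_mm`` (r) set the two
    spheres, ``indent_depth_mm`` (t) the intended maximum defect depth, and
    ``indent_direction`` the unit vector from the condyle center toward the
    defect apex.  ``slice_spacing_mm`` / ``in_plane_step_mm`` mirror the
    acquisition geometry of clinical sagittal MRI (spacing 3.0–4.8 mm,
    in-plane resolution 0.29–0.70 mm); the defaults are much finer so that
    sampling error is negligible against the closed forms.
    """

    condyle_radius_mm: float = 20.0
    indent_radius_mm: float = 10.0
    indent_depth_mm: float = 3.0
    indent_direction: tuple = (0.0, 0.0, -1.0)
    ml_extent_mm: float = 15.0
    slice_spacing_mm: float = 0.5
    in_plane_step_mm: float = 0.1
    noise_sd_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        R, r, t = self.condyle_radius_mm, self.indent_radius_mm, self.indent_depth_mm
        if R <= 0 or r <= 0:
            raise ValueError("sphere radii must be positive")
        if not 0 <= t < min(r, R):
            raise ValueError("indent depth must satisfy 0 <= t < min(r, R)")
        if self.slice_spacing_mm <= 0 or self.in_plane_step_mm <= 0:
            raise ValueError("sampling steps must be positive")
        if not 0 < self.ml_extent_mm < R:
            raise ValueError("ml_extent_mm must lie strictly inside the sphere radius")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be non-negative")
        u = np.asarray(self.indent_direction, dtype=float)
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            raise ValueError("indent_direction is degenerate")
        object.__setattr__(self, "indent_direction", tuple(u / norm))


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form twin of the measured quantities."""

    defect_depth_mm: float
    primary_area_mm2: float
    concave_area_mm2: float
    volume_mm3: float
    footprint_radius_mm: float
    total_surface_area_mm2: float | None = None
    landmarks: Landmarks | None = field(default=None)


def analytic_lens_metrics(R: float, r: float, t: float) -> PhantomTruth:
    """Closed-form defect metrics for an indent of depth t (sphere–sphere lens).

    The indenting sphere's center sits at d = R + r − t from the condyle
    center; the boundary circle lies on the plane at
    x_R = (d² − r² + R²)/(2d), giving cap heights h_R = R − x_R on the condyle
    and h_r = r − (d − x_R) on the indenter.  Areas follow Archimedes
    (2πρh), the volume is the standard lens formula.
    """
    if not 0 <= t < min(r, R):
        raise ValueError("invalid geometry: need 0 <= t < min(r, R)")
    if t == 0:
        return PhantomTruth(0.0, 0.0, 0.0, 0.0, 0.0)
    d = R + r - t
    x_R = (d * d - r * r + R * R) / (2 * d)
    h_R = R - x_R
    h_r = r - (d - x_R)
    volume = (
        np.pi
        * (R + r - d) ** 2
        * (d * d + 2 * d * r - 3 * r * r + 2 * d * R + 6 * r * R - 3 * R * R)
        / (12 * d)
    )
    return PhantomTruth(
        defect_depth_mm=t,
        primary_area_mm2=2 * np.pi * R * h_R,
        concave_area_mm2=2 * np.pi * r * h_r,
        volume_mm3=float(volume),
        footprint_radius_mm=float(np.sqrt(R * R - x_R * x_R)),
    )


def analytic_zone_area(R: float, x_lo: float, x_hi: float) -> float:
    """Area of the spherical zone between two parallel planes (hat-box: 2πRΔx)."""
    if not -R <= x_lo < x_hi <= R:
        raise ValueError("zone bounds must satisfy -R <= x_lo < x_hi <= R")
    return 2 * np.pi * R * (x_hi - x_lo)


def _slice_circle(rho: float, step: float) -> np.ndarray:
    """Near-closed circle of radius rho, seam at SEAM_ANGLE, step ~ given."""
    m = max(8, int(np.ceil(2 * np.pi * rho / step)))
    phi = np.arange(m) * (2 * np.pi / m)
    psi = SEAM_ANGLE - phi  # traverse anterior → distal → posterior → proximal
    return rho * np.column_stack([np.cos(psi), np.sin(psi)])


def generate_phantom(spec: PhantomSpec) -> tuple[list[SliceContour], PhantomTruth]:
    """Sample the phantom into annotated slice contours plus its ground truth.

    Slices intersecting the indenting sphere carry a :class:`DefectMark`
    whose interior vertices are exactly the points projected onto the
    indenter; endpoints are the adjacent intact vertices.  Output is
    deterministic for a given spec (noise is drawn from a generator seeded
    with ``spec.seed``).
    """
    R = spec.condyle_radius_mm
    r = spec.indent_radius_mm
    t = spec.indent_depth_mm
    u = np.asarray(spec.indent_direction)
    d = R + r - t
    center = d * u

    positions = np.arange(
        -spec.ml_extent_mm, spec.ml_extent_mm + 1e-9, spec.slice_spacing_mm
    )
    if len(positions) < 2:
        raise ValueError("modeled zone is narrower than one slice spacing")
    rng = np.random.default_rng(spec.seed)

    slices: list[SliceContour] = []
    for x in positions:
        rho = float(np.sqrt(R * R - x * x))
        pts = _slice_circle(rho, spec.in_plane_step_mm)
        mark = None
        dx = x - center[0]
        if t > 0 and abs(dx) < r:
            rc = float(np.sqrt(r * r - dx * dx))
            c2 = center[1:]
            dist = np.linalg.norm(pts - c2, axis=1)
            inside = dist < rc
            if inside.any():
                idx = np.flatnonzero(inside)
                if np.any(np.diff(idx) > 1):
                    raise ValueError(
                        "defect interval wraps across the contour seam; choose an "
                        "indent_direction away from the anterior-proximal seam"
                    )
                safe = np.maximum(dist[inside], 1e-12)[:, None]
                pts[inside] = c2 + rc * (pts[inside] - c2) / safe
                i0, i1 = int(idx[0]), int(idx[-1])
                if i0 > 0 and i1 < len(pts) - 1:
                    mark = DefectMark(i0 - 1, i1 + 1)
                else:
                    raise ValueError(
                        "defect interval touches the contour seam; choose an "
                        "indent_direction away from the anterior-proximal seam"
                    )
        if spec.noise_sd_mm > 0:
            pts = pts + rng.normal(0.0, spec.noise_sd_mm, pts.shape)
        slices.append(
            SliceContour(float(x), pts, spec.slice_spacing_mm, mark=mark)
        )

    ml = spec.ml_extent_mm
    rho_edge = float(np.sqrt(R * R - ml * ml))
    landmarks = Landmarks(
        trochlear_notch_point=np.array(
            [0.0, R * np.cos(SEAM_ANGLE), R * np.sin(SEAM_ANGLE)]
        ),
        posterior_point_medial=np.array([-ml, -rho_edge, 0.0]),
        posterior_point_lateral=np.array([ml, -rho_edge, 0.0]),
        shaft_axis_direction=np.array([0.0, 0.0, 1.0]),
    )
    lens = analytic_lens_metrics(R, r, t)
    truth = PhantomTruth(
        defect_depth_mm=lens.defect_depth_mm,
        primary_area_mm2=lens.primary_area_mm2,
        concave_area_mm2=lens.concave_area_mm2,
        volume_mm3=lens.volume_mm3,
        footprint_radius_mm=lens.footprint_radius_mm,
        total_surface_area_mm2=analytic_zone_area(R, -ml, ml),
        landmarks=landmarks,
    )
    return slices, truth


def clinical_spec(**overrides) -> PhantomSpec:
    """Phantom spec at clinical-like acquisition geometry (3.3 mm slice
    spacing, 0.31 mm in-plane resolution)."""
    kw = dict(slice_spacing_mm=3.3, in_plane_step_mm=0.31)
    kw.update(overrides)
    return PhantomSpec(**kw)


def sulcus_profile(
    R: float = 20.0,
    r: float = 10.0,
    t: float = 3.0,
    span_deg: float = 120.0,
    step: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """2D lateral-radiograph condyle profile with a spherical-indent dip.

    Returns the profile (anterior→posterior point sequence on a circle of
    radius R with an indentation of construction depth t) together with its
    closed-form measurement truth.  Note that the depth below the tangential
    hull chord is x_R − (R − t), i.e. less than t by the chord's sagitta
    h_R — the two coincide only for straight flanks.
    """
    half = np.radians(span_deg) / 2
    n = max(16, int(np.ceil(np.radians(span_deg) * R / step)) + 1)
    theta = np.linspace(half, -half, n)  # anterior → posterior around the dip apex
    # Apex direction is -y2 in local (x2, y2) profile coordinates.
    pts = R * np.column_stack([np.sin(theta), -np.cos(theta)])
    truth = {"tangent_depth_mm": 0.0, "construction_depth_mm": t}
    if t > 0:
        lens = analytic_lens_metrics(R, r, t)
        d = R + r - t
        c2 = np.array([0.0, -d])
        dist = np.linalg.norm(pts - c2, axis=1)
        inside = dist < r
        pts[inside] = c2 + r * (pts[inside] - c2) / dist[inside][:, None]
        x_R = (d * d - r * r + R * R) / (2 * d)
        truth["tangent_depth_mm"] = x_R - (R - t)
        truth["footprint_radius_mm"] = lens.footprint_radius_mm
    return pts, truth
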