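"""Lateral-radiograph sulcus-depth measurement and notch-sign classification.

The condylopatellar sulcus depth is measured by drawing a tangential line
across the sulcus on the articular profile of the lateral femoral condyle and
taking the maximum perpendicular distance from that line to the profile at
its deepest point.  A depth at or above 1.5 mm constitutes the lateral
femoral notch sign; intact knees average around 0.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import as_points, hull_concavities

__all__ = [
    "NOTCH_THRESHOLD_MM",
    "SulcusProfile",
    "SulcusMeasurement",
    "measure_sulcus_depth",
    "classify_notch_sign",
]

#: Screening threshold (mm); the comparison is inclusive (depth >= threshold).
NOTCH_THRESHOLD_MM = 1.5

_ONLINE_TOL = 1e-9


@dataclass(frozen=True)
class SulcusProfile:
    """Digitized articular margin of the lateral condyle, anterior→posterior.

    ``points`` are ordered 2D coordinates in mm.  ``orientation`` declares the
    articular side: "bone-right" means the bone lies to the right of the
    traversal direction (the convention of an anterior→posterior trace of the
    lateral condyle's articular margin with the joint space on the left);
    "bone-left" is the mirrored trace.
    """

    points: np.ndarray
    orientation: str = "bone-right"

    def __post_init__(self):
        if self.orientation not in ("bone-right", "bone-left"):
            raise ValueError("orientation must be 'bone-right' or 'bone-left'")
        pts = as_points(self.points)
        if len(pts) < 3:
            raise ValueError("sulcus profile needs at least 3 points")
        if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) <= 0):
            raise ValueError("consecutive profile points must be distinct")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class SulcusMeasurement:
    """Result of the tangential-line depth measurement."""

    depth_mm: float
    tangent_segment: np.ndarray  # (2, 2) endpoints of the tangential line
    deepest_point: np.ndarray | None
    notch_sign: bool


def measure_sulcus_depth(
    profile: SulcusProfile, threshold: float = NOTCH_THRESHOLD_MM
) -> SulcusMeasurement:
    """Measure the sulcus depth of a condyle profile.

    The tangential line is the convex-hull edge spanning the concavity with
    the greatest perpendicular deviation (ties go to the more anterior
    concavity); the depth is that deviation at the deepest point.  A convex
    profile has depth 0 and reports its longest hull edge as the tangent.
    """
    pts = profile.points
    concs = hull_concavities(pts, bone_side=profile.orientation.split("-")[1])
    best = None
    for c in concs:
        if c.depth <= _ONLINE_TOL:
            continue
        if best is None or c.depth > best.depth + _ONLINE_TOL:
            best = c
    if best is None:
        # Convex (or collinear) profile: no sulcus.
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        j = int(np.argmax(seg))
        tangent = np.vstack([pts[j], pts[j + 1]])
        return SulcusMeasurement(0.0, tangent, None, classify_notch_sign(0.0, threshold))
    tangent = np.vstack([pts[best.start], pts[best.end]])
    return SulcusMeasurement(
        depth_mm=best.depth,
        tangent_segment=tangent,
        deepest_point=pts[best.deepest],
        notch_sign=classify_notch_sign(best.depth, threshold),
    )


def classify_notch_sign(depth_mm: float, threshold: float = NOTCH_THRESHOLD_MM) -> bool:
    """True iff the sulcus depth reaches the notch-sign threshold (inclusive)."""
    if depth_mm < 0:
        raise ValueError("sulcus depth must be non-negative")
    return depth_mm >= threshold
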