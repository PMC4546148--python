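"""Shared planar-curve helpers: arc length, resampling, convex-hull concavities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

#: Vertices within this perpendicular distance (mm) of a hull edge count as
#: lying on the tangential line rather than deviating from it.
ONLINE_TOL = 1e-9


def cross2(e, v):
    """z-component of the cross product of 2D vectors (v may be (n, 2))."""
    e = np.asarray(e)
    v = np.asarray(v)
    return e[..., 0] * v[..., 1] - e[..., 1] * v[..., 0]


def as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative chord length along a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to k points uniformly spaced in arc length."""
    points = as_points(points)
    if k < 2:
        raise ValueError("need at least 2 resample points")
    s = cumulative_arclength(points)
    if s[-1] <= 0:
        return np.repeat(points[:1], k, axis=0)
    target = np.linspace(0.0, s[-1], k)
    out = np.empty((k, 2))
    for c in range(2):
        out[:, c] = np.interp(target, s, points[:, c])
    return out


@dataclass(frozen=True)
class Concavity:
    """A convex-hull edge spanning a deviation of the curve into the hull interior.

    ``start``/``end`` are curve vertex indices of the hull-touching endpoints,
    ``depth`` the maximum perpendicular distance of the spanned vertices from the
    edge, ``deepest`` the index attaining it.
    """

    start: int
    end: int
    depth: float
    deepest: int


def hull_concavities(points: np.ndarray, bone_side: str = "right") -> list[Concavity]:
    """Enumerate concavities of an open articular curve via its convex hull.

    The hull of the ordered point set is traversed in curve order; every hull
    edge that skips intermediate curve vertices is a candidate tangent whose
    concavity depth is the largest perpendicular deviation of the skipped
    vertices toward the bone.  ``bone_side`` declares on which side of the
    traversal direction the bone lies ("right" for a profile traced with the
    joint space on its left, the convention of an anterior→posterior articular
    trace); edges whose skipped vertices deviate toward the joint space (the
    hull's closing chord of a convex arc, the side walls of a dip that is
    itself extremal) are rejected.  The closing edge between the first and
    last hull vertex is itself a candidate — it is the tangential line when
    the dip forms part of the hull, as on a near-straight profile.  Edge
    endpoints are trimmed inward over vertices collinear with the edge, so
    the reported tangent touches the bone at the points flanking the
    concavity.  Collinear input yields no concavities.
    """
    if bone_side not in ("right", "left"):
        raise ValueError("bone_side must be 'right' or 'left'")
    sign = -1.0 if bone_side == "right" else 1.0
    points = as_points(points)
    n = len(points)
    if n < 3:
        return []
    try:
        hull = ConvexHull(points)
    except QhullError:
        return []  # degenerate (collinear) profile: everything is on the hull
    verts = list(hull.vertices)  # counter-clockwise order
    # Rotate to start at the smallest curve index, then orient so that curve
    # indices increase along the traversal (minus the final wrap edge).
    k0 = int(np.argmin(verts))
    verts = verts[k0:] + verts[:k0]
    forward = verts
    backward = [verts[0]] + verts[1:][::-1]
    for order in (forward, backward):
        if all(b > a for a, b in zip(order, order[1:])):
            break
    else:
        raise ValueError(
            "profile is too convoluted for hull-based concavity analysis"
        )
    out: list[Concavity] = []
    candidates = list(zip(order, order[1:]))
    if len(order) >= 2:
        candidates.append((order[0], order[-1]))  # hull closing edge
    for a, b in candidates:
        if b - a <= 1:
            continue
        pa, pb = points[a], points[b]
        e = pb - pa
        norm = np.linalg.norm(e)
        if norm <= 0:
            continue
        mid = points[a + 1 : b]
        # Positive = deviation toward the bone side of the edge direction.
        dev = sign * cross2(e, mid - pa) / norm
        j = int(np.argmax(dev))
        if dev[j] <= ONLINE_TOL:
            continue  # skipped vertices deviate toward the joint space
        # Trim endpoints inward over vertices lying on the edge line, so the
        # tangent touches the bone at the vertices flanking the concavity.
        off = np.flatnonzero(np.abs(dev) > ONLINE_TOL)
        lo, hi = off[0], off[-1]
        on_left = np.flatnonzero(np.abs(dev[:lo]) <= ONLINE_TOL)
        on_right = np.flatnonzero(np.abs(dev[hi + 1 :]) <= ONLINE_TOL)
        a_trim = a + 1 + int(on_left[-1]) if len(on_left) else a
        b_trim = a + 1 + hi + 1 + int(on_right[0]) if len(on_right) else b
        out.append(Concavity(int(a_trim), int(b_trim), float(dev[j]), int(a + 1 + j)))
    return out


def point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    e = b - a
    norm = np.linalg.norm(e)
    if norm <= 0:
        return float(np.linalg.norm(p - a))
    return float(abs(cross2(e, p - a)) / norm)


def rotation_2d(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s], [s, c]])
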