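"""Segmentation exchange format: versioned JSON for planar contour stacks.

No standard file format exists for stacks of open planar segmentation
contours, so the toolkit defines a small JSON dialect with explicit units
(mm) and an explicit axis convention in the header.  Readers validate every
invariant on load and reject unknown versions; writers produce byte-stable
output so identical inputs give identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .regions import Landmarks
from .slicegeom import DefectMark, SliceContour

__all__ = ["FORMAT_VERSION", "SegmentationError", "read_segmentation", "write_segmentation"]

FORMAT_VERSION = "condyle-seg/1"
AXES = {"x": "medial->lateral", "y": "posterior->anterior", "z": "distal->proximal"}


class SegmentationError(ValueError):
    """Malformed or unsupported segmentation file."""


def write_segmentation(
    path,
    slices: list[SliceContour],
    landmarks: Landmarks | None = None,
    knee_id: str = "unknown",
    meta: dict | None = None,
) -> None:
    doc = {
        "format": FORMAT_VERSION,
        "units": "mm",
        "axes": AXES,
        "knee_id": knee_id,
        "meta": meta or {},
        "landmarks": None
        if landmarks is None
        else {
            "trochlear_notch": landmarks.trochlear_notch_point.tolist(),
            "posterior_medial": landmarks.posterior_point_medial.tolist(),
            "posterior_lateral": landmarks.posterior_point_lateral.tolist(),
            "shaft_axis": landmarks.shaft_axis_direction.tolist(),
        },
        "slices": [
            {
                "x_ml_mm": s.x_ml_mm,
                "spacing_mm": s.slice_spacing_mm,
                "defect_mark": None
                if s.mark is None
                else [s.mark.start_index, s.mark.end_index],
                "points": np.asarray(s.points).tolist(),
            }
            for s in sorted(slices, key=lambda s: s.x_ml_mm)
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_segmentation(path) -> tuple[Landmarks | None, list[SliceContour]]:
    """Load and fully validate a segmentation file.

    Returns the landmark block (``None`` if absent) and the slice contours in
    strictly increasing medio-lateral order.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SegmentationError(f"{path}: not valid JSON ({e})") from e
    version = doc.get("format")
    if version != FORMAT_VERSION:
        raise SegmentationError(
            f"{path}: unsupported format version {version!r} (expected {FORMAT_VERSION!r})"
        )
    raw_slices = doc.get("slices")
    if not isinstance(raw_slices, list) or not raw_slices:
        raise SegmentationError(f"{path}: missing or empty 'slices' block")

    slices = []
    for i, raw in enumerate(raw_slices):
        try:
            mark = raw.get("defect_mark")
            slices.append(
                SliceContour(
                    x_ml_mm=float(raw["x_ml_mm"]),
                    points=np.asarray(raw["points"], dtype=float),
                    slice_spacing_mm=float(raw["spacing_mm"]),
                    mark=None if mark is None else DefectMark(int(mark[0]), int(mark[1])),
                )
            )
        except (KeyError, TypeError, ValueError) as e:
            raise SegmentationError(f"{path}: slice {i}: {e}") from e
    xs = [s.x_ml_mm for s in slices]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise SegmentationError(
            f"{path}: slice positions must be strictly increasing (got {xs})"
        )

    lm = doc.get("landmarks")
    landmarks = None
    if lm is not None:
        try:
            landmarks = Landmarks(
                trochlear_notch_point=np.asarray(lm["trochlear_notch"], dtype=float),
                posterior_point_medial=np.asarray(lm["posterior_medial"], dtype=float),
                posterior_point_lateral=np.asarray(lm["posterior_lateral"], dtype=float),
                shaft_axis_direction=np.asarray(lm["shaft_axis"], dtype=float),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise SegmentationError(f"{path}: landmark block: {e}") from e
    return landmarks, slices
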