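"""Cohort screening, aggregation and internal-consistency arithmetic.

Knee records enter via the radiographic screen (sulcus depth >= 1.5 mm with
MRI confirmation of the notch sign), are summarized as per-variable means and
standard deviations plus a per-segment mean table, and the summary's
additivity (segment sums reproducing cohort totals, unit pairings,
percentage arithmetic) is verified by explicit consistency checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry3d import CondyleMetrics, DefectMetrics
from .regions import REGION_LABELS, SegmentMetrics

__all__ = [
    "KneeRecord",
    "CohortSummary",
    "CheckResult",
    "ConsistencyReport",
    "screen_cohort",
    "summarize_cohort",
    "consistency_checks",
    "cohort_frame",
]

MEAN_FIELDS = ("total_area_cm2",) + DefectMetrics.FIELDS
NO_DEFECT = "NONE"


@dataclass(frozen=True)
class KneeRecord:
    """One knee's screening data, defect metrics and regional attribution."""

    knee_id: str
    defect: DefectMetrics
    total: CondyleMetrics
    segments: tuple
    location: str | None
    sulcus_depth_mm: float | None = None
    mri_notch_confirmed: bool | None = None

    def __post_init__(self):
        segs = tuple(self.segments)
        labels = tuple(s.region for s in segs)
        if sorted(labels) != sorted(REGION_LABELS):
            raise ValueError(
                f"knee {self.knee_id}: segments must cover exactly {REGION_LABELS}"
            )
        object.__setattr__(self, "segments", segs)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level means/SDs, six-segment mean table and location frequencies.

    ``segment_table`` is indexed by region label with the
    :class:`~notchmorph.regions.SegmentMetrics` columns; ``means_mm2``
    optionally carries mm²-scale duplicates of area means (as printed in
    clinical reports) for unit-pairing checks.
    """

    n: int
    means: dict
    sds: dict
    segment_table: pd.DataFrame
    location_freq: dict = field(default_factory=dict)
    means_mm2: dict | None = None

    def __post_init__(self):
        if self.location_freq:
            tot = sum(self.location_freq.values())
            if abs(tot - 100.0) > 0.1:
                raise ValueError(f"location frequencies sum to {tot}, not 100")


def screen_cohort(records: list[KneeRecord], threshold: float = 1.5) -> list[KneeRecord]:
    """Keep knees with sulcus depth >= threshold and MRI-confirmed notch sign."""
    missing = [
        r.knee_id
        for r in records
        if r.sulcus_depth_mm is None or r.mri_notch_confirmed is None
    ]
    if missing:
        raise ValueError(f"records missing screening fields: {', '.join(missing)}")
    return [
        r
        for r in records
        if r.sulcus_depth_mm >= threshold and r.mri_notch_confirmed
    ]


def summarize_cohort(records: list[KneeRecord]) -> CohortSummary:
    """Arithmetic means and sample SDs (n−1) over a cohort of knee records.

    Per-segment means average over *all* knees, counting zero contributions —
    the convention under which segment columns sum to the cohort totals.
    SDs are reported as ``None`` for a single-knee cohort.
    """
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    n = len(records)

    def col(getter):
        return np.array([getter(r) for r in records], dtype=float)

    means, sds = {}, {}
    for name in MEAN_FIELDS:
        vals = col(
            (lambda r, name=name: r.total.total_area_cm2)
            if name == "total_area_cm2"
            else (lambda r, name=name: getattr(r.defect, name))
        )
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=1)) if n > 1 else None

    rows = []
    for lab in REGION_LABELS:
        row = {"region": lab}
        for fieldname in SegmentMetrics.FIELDS:
            vals = []
            for r in records:
                seg = next(s for s in r.segments if s.region == lab)
                vals.append(getattr(seg, fieldname))
            row[fieldname] = float(np.mean(vals))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("region")

    locs = [r.location if r.location is not None else NO_DEFECT for r in records]
    freq = {lab: 100.0 * locs.count(lab) / n for lab in sorted(set(locs))}
    return CohortSummary(n=n, means=means, sds=sds, segment_table=table, location_freq=freq)


@dataclass(frozen=True)
class CheckResult:
    name: str
    computed: float
    expected: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.expected) <= self.tol


@dataclass(frozen=True)
class ConsistencyReport:
    checks: tuple

    @property
    def all_pass(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = ["Internal-consistency checks"]
        for c in self.checks:
            status = "pass" if c.passed else "FAIL"
            lines.append(
                f"  [{status}] {c.name}: computed {c.computed:.4f} "
                f"vs expected {c.expected:.4f} (tol {c.tol:g})"
            )
        lines.append(f"Overall: {'all pass' if self.all_pass else 'FAILURES present'}")
        return "\n".join(lines)


def consistency_checks(
    summary: CohortSummary, value_tol: float = 0.05, sum_tol: float = 0.15
) -> ConsistencyReport:
    """Verify the summary's internal arithmetic.

    Checks that the six segment columns sum to the cohort totals (surface,
    affected/primary area, concave area, volume), that the condyle percentage
    equals 100 × affected/total, and that any mm²-scale duplicates pair with
    their cm² values.  Sums of six independently rounded values carry
    ``sum_tol`` (default ±0.15, three times the half-unit of one printed
    decimal); single-value comparisons carry ``value_tol`` (±0.05).
    Failures are reported, never raised.
    """
    t = summary.segment_table
    m = summary.means
    checks = [
        CheckResult(
            "segment surfaces sum to total condyle surface (cm^2)",
            float(t["region_surface_cm2"].sum()),
            m["total_area_cm2"],
            sum_tol,
        ),
        CheckResult(
            "segment affected areas sum to total primary area (cm^2)",
            float(t["affected_area_cm2"].sum()),
            m["primary_area_cm2"],
            sum_tol,
        ),
        CheckResult(
            "segment concave areas sum to total concave area (cm^2)",
            float(t["concave_area_cm2"].sum()),
            m["concave_area_cm2"],
            sum_tol,
        ),
        CheckResult(
            "segment volumes sum to total defect volume (mm^3)",
            float(t["volume_mm3"].sum()),
            m["volume_mm3"],
            sum_tol,
        ),
        CheckResult(
            "percent of condyle equals 100 x primary/total",
            100.0 * m["primary_area_cm2"] / m["total_area_cm2"],
            m["percent_of_condyle"],
            value_tol,
        ),
    ]
    if summary.means_mm2:
        for key, mm2 in summary.means_mm2.items():
            checks.append(
                CheckResult(
                    f"unit pairing {key}: mm^2/100 matches cm^2",
                    mm2 / 100.0,
                    m[key],
                    value_tol,
                )
            )
    return ConsistencyReport(tuple(checks))


def cohort_frame(records: list[KneeRecord]) -> pd.DataFrame:
    """One row per knee: totals, defect metrics, location, per-segment columns."""
    rows = []
    for r in records:
        row = {
            "knee_id": r.knee_id,
            "sulcus_depth_mm": r.sulcus_depth_mm,
            "mri_notch_confirmed": r.mri_notch_confirmed,
            "total_area_cm2": r.total.total_area_cm2,
            "location": r.location if r.location is not None else NO_DEFECT,
        }
        for name in DefectMetrics.FIELDS:
            row[name] = getattr(r.defect, name)
        for seg in sorted(r.segments, key=lambda s: REGION_LABELS.index(s.region)):
            for name in SegmentMetrics.FIELDS:
                row[f"{seg.region}_{name}"] = getattr(seg, name)
        rows.append(row)
    return pd.DataFrame(rows)


def record_from_slices(
    knee_id: str,
    slices,
    landmarks=None,
    sulcus_depth_mm: float | None = None,
    mri_notch_confirmed: bool | None = None,
    k: int = 200,
) -> KneeRecord:
    """Run the full per-knee pipeline on marked slice contours.

    Computes the whole-condyle surface, defect metrics and — when landmarks
    are available — the six-segment attribution and primary-location call;
    without landmarks the segments default to all-zero rows so the record
    still satisfies its schema.
    """
    from .morphometry3d import bridge_marked_slices, defect_metrics, total_surface_area
    from .regions import (
        REGION_LABELS,
        SegmentMetrics,
        assign_regions,
        build_partition,
        classify_primary_location,
    )

    slices = sorted(slices, key=lambda s: s.x_ml_mm)
    total = total_surface_area(slices, k=k)
    bridged = bridge_marked_slices(slices)
    defect = defect_metrics(bridged, total, k=k)
    if landmarks is not None:
        partition = build_partition(slices, landmarks)
        segments = assign_regions(partition, slices, bridged, k=k)
        location = classify_primary_location(segments)
    else:
        segments = [SegmentMetrics.zeros(lab) for lab in REGION_LABELS]
        location = None
    return KneeRecord(
        knee_id=knee_id,
        defect=defect,
        total=total,
        segments=tuple(segments),
        location=location,
        sulcus_depth_mm=sulcus_depth_mm,
        mri_notch_confirmed=mri_notch_confirmed,
    )
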