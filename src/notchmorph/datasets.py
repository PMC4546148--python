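"""Published reference values for a 50-knee notch-sign cohort.

A clinical study of ACL-injured knees screened 422 radiographs, found 64 with
a condylopatellar sulcus deeper than 1.5 mm, excluded 14 without MRI
confirmation, and segmented the remaining 50.  Its printed cohort means —
whole-condyle surface, defect metrics and the six-segment regional table —
are reproduced here as data, used to exercise the cohort module's
internal-consistency arithmetic.  The underlying images are not public, so
these numbers are inputs, not recomputable results.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortSummary

__all__ = [
    "SEGMENT_TABLE_ROWS",
    "COHORT_MEANS",
    "COHORT_MEANS_MM2",
    "SCREENING_COUNTS",
    "reference_summary",
]

# Six-segment mean table (50 knees): region surface cm², defect length mm
# (a.p.), width mm (m.l.), depth mm, affected area cm², percent of region,
# concave area cm², volume mm³.
SEGMENT_TABLE_ROWS = {
    "CE": dict(region_surface_cm2=4.0, defect_length_mm=10.7, defect_width_mm=13.0,
               defect_depth_mm=2.8, affected_area_cm2=0.9, percent_of_region=0.3,
               concave_area_cm2=1.3, volume_mm3=221.0),
    "CI": dict(region_surface_cm2=3.2, defect_length_mm=8.6, defect_width_mm=4.7,
               defect_depth_mm=2.2, affected_area_cm2=0.2, percent_of_region=0.08,
               concave_area_cm2=0.5, volume_mm3=85.3),
    "AE": dict(region_surface_cm2=6.6, defect_length_mm=7.3, defect_width_mm=11.0,
               defect_depth_mm=2.1, affected_area_cm2=0.5, percent_of_region=0.07,
               concave_area_cm2=0.7, volume_mm3=120.8),
    "AI": dict(region_surface_cm2=8.4, defect_length_mm=3.4, defect_width_mm=3.3,
               defect_depth_mm=1.5, affected_area_cm2=0.06, percent_of_region=0.008,
               concave_area_cm2=0.2, volume_mm3=28.2),
    "PE": dict(region_surface_cm2=6.8, defect_length_mm=0.1, defect_width_mm=0.2,
               defect_depth_mm=0.1, affected_area_cm2=0.004, percent_of_region=0.001,
               concave_area_cm2=0.007, volume_mm3=1.3),
    "PI": dict(region_surface_cm2=3.7, defect_length_mm=0.0, defect_width_mm=0.0,
               defect_depth_mm=0.0, affected_area_cm2=0.0, percent_of_region=0.0,
               concave_area_cm2=0.0, volume_mm3=0.0),
}

# Cohort means (n = 50), cm²/mm/mm³ scale as printed.
COHORT_MEANS = dict(
    total_area_cm2=32.7,
    primary_area_cm2=1.7,       # area affected by the impaction fracture
    concave_area_cm2=2.7,       # surface area of the defect itself
    volume_mm3=456.5,
    depth_mm=3.0,
    percent_of_condyle=5.2,
    ap_length_mm=0.0,           # not reported at cohort level
    ml_width_mm=0.0,
)

# The same area means on the mm² scale, as printed alongside.
COHORT_MEANS_MM2 = dict(
    total_area_cm2=3271.7,
    concave_area_cm2=266.1,
    primary_area_cm2=169.0,
)

# Radiographic screening funnel.
SCREENING_COUNTS = dict(radiograph_positive=64, mri_excluded=14, analyzed=50)

#: Share of knees whose primary defect location was called central-external.
LOCATION_CE_PERCENT = 51.0


def reference_summary() -> CohortSummary:
    """The published cohort summary assembled as a :class:`CohortSummary`."""
    table = pd.DataFrame.from_dict(SEGMENT_TABLE_ROWS, orient="index")
    table.index.name = "region"
    return CohortSummary(
        n=SCREENING_COUNTS["analyzed"],
        means=dict(COHORT_MEANS),
        sds={},
        segment_table=table,
        location_freq={},
        means_mm2=dict(COHORT_MEANS_MM2),
    )
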