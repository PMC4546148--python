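# Methods

This note records the models, conventions and numerical choices behind
notchmorph, and what the phantom validation does and does not establish.

## Coordinate and data conventions

All lengths are millimetres. Axes: x = medial→lateral, y =
posterior→anterior, z = distal→proximal. Sagittal slices are planes of
constant x; each segmentation is an *open* polyline (the articular
subchondral surface is a sheet, never a closed polygon), ordered along arc
length and traced with the bone on the right of the travel direction
(anterior → distal → posterior). Areas are reported in cm² (mm²/100),
volumes in mm³, with one-decimal rounding in reports and full precision in
machine output.

## Radiographic sulcus depth

The tangential line is found on the convex hull of the digitized profile:
every hull edge that skips profile vertices is a candidate, and a candidate
is valid when the skipped vertices deviate toward the bone side declared by
the profile's orientation flag (`bone-right`/`bone-left`). Both regimes
occur in practice: on a curved condyle profile the dip deviates into the
hull interior, while on a near-straight profile the dip itself is
hull-extremal and the tangent is the hull's closing edge. Edge endpoints
are trimmed inward over collinear run-ins (tolerance 1e-9 mm) so the
tangent touches the bone at the points flanking the sulcus. Among valid
concavities the deepest wins; ties go to the more anterior one. The notch
threshold (default 1.5 mm) is applied inclusively — the boundary case is
positive — and is configurable, since both inclusive and exclusive
phrasings circulate; the inclusive headline reading was adopted.

Note that for a dip carved by a sphere of radius r to depth t into a
condyle of radius R, the depth below the tangential chord is
x_R − (R − t) with x_R = (d² − r² + R²)/(2d), d = R + r − t — *less* than t
by the chord's sagitta. Depth-below-tangent equals the construction depth
only for straight flanks, which is also exactly when the radiographic
measurement agrees with the slice-wise depth below the bridging contour.

## Slice-wise bridging

The bridge is a cubic interpolating spline through up to `n_flank = 5`
contour vertices on each side of the marked interval, parameterized by
cumulative chord length and evaluated across the gap at the contour's
native point density; when the flanks are collinear within 1e-6 mm it falls
back to the straight chord. A flank-constrained spline is the simplest
faithful realisation of "a contour approximating the bone surface under
normal anatomical conditions", and 5 vertices per side keeps the fit local.
On a circle of radius 20 mm with a 12 mm gap the spline deviates from the
true circle by ≈ 0.02 mm (the gap is a single knot interval, so the error
scales with gap⁴). Depth is measured perpendicular to the bridge (maximum
distance from depressed vertices to the bridge polyline), not along the
image vertical — the paper-style manual convention is ambiguous, and the
perpendicular reading is rotation invariant. The gap area is the planar
area of the polygon formed by the bridge and the reversed depressed curve
(shapely); a self-intersecting polygon is an error naming the slice,
a degenerate one has zero area.

Expert marks in the input files are authoritative; automatic detection
(`detect_defect_interval`) is opt-in and flags the deepest hull concavity
exceeding 0.3 mm — below the finest clinical in-plane resolution
(0.29 mm), so sampling jitter alone cannot trigger a mark.

## 3D reconstruction and metrics

Adjacent contours are resampled to K = 200 points by arc length and joined
into triangle strips (arc-length-proportional correspondence), the standard
construction for stacked-contour bone/cartilage morphometry; no end caps
(open sheet), no smoothing. Whole-condyle area uses the bridged ("healthy
reference") curves. The defect volume is the trapezoidal integral of gap
areas over slice positions, tapered to zero one slice spacing beyond the
outermost defect-bearing slices; a single-slice defect contributes one full
slab (area × spacing). The medio-lateral width adds one slice spacing to
the position span for the same slab reasoning, and the antero-posterior
length is the y-projection extent of the marked interval, maximized over
slices (extents are axis projections, not 3D chords). A defect confined to
a single slice has zero strip area but nonzero width and volume — areas
need at least two bearing slices.

## Regional partition

Plane 1 passes through the trochlear notch, spanned by the shaft axis and
the vector between the two posterior-most points; its normal is oriented
anteriorly. Plane 2 is parallel at 60 % of the signed notch→posterior
distance, measured from the notch, so the central (weight-bearing) band
spans 0–60 % of that distance behind plane 1. The medio-lateral split is
the midpoint of the *segmented surface's* slice-position range (not the
defect's). Surface triangles are assigned whole, by centroid — no triangle
splitting, so segment sums equal totals exactly and the assignment error of
boundary-straddling triangles vanishes with mesh refinement. Segment
volumes are computed by clipping each slice's gap polygon at the two plane
traces (exact polygon intersection), keeping the volume additive as well.
The per-knee location call is the segment with the largest affected
(primary) area; ties break CE, CI, AE, AI, PE, PI, ordered by reported
clinical prevalence.

## Phantom model

The condyle is a sphere of radius R (default 20 mm); the modeled zone is
the band |x| ≤ 15 mm, sampled as near-closed circles (one in-plane step of
opening at the anterior-proximal 45° seam, where the bone would continue
into the shaft). This makes the zone's area the Archimedes hat-box value
2πRΔx, the analytic oracle for total surface area. The defect is realized
by projecting, within each slice plane, every contour point inside the
indenting sphere (radius r = 10 mm, center at distance d = R + r − t along
the indent direction) onto that sphere — the union of the in-plane
projections is exactly the indenter's spherical cap, so:

- primary area = cap on the condyle sphere: 2πR·h_R, h_R = R − x_R
- concave area = cap on the indenter: 2πr·h_r, h_r = r − (d − x_R)
- volume = sphere–sphere lens: π t² (d² + 2dr − 3r² + 2dR + 6rR − 3R²)/(12d)
- maximum depth = t; footprint radius a = √(R² − x_R²)

For (R, r, t) = (20, 10, 3): 118.68 mm², 129.15 mm², 178.81 mm³,
a = 6.07 mm; the volume was confirmed against a 0.05 mm voxelization
(0.02 % agreement). Landmarks are analytic: the trochlear-notch stand-in at
the seam of the central slice, the posterior-most points of the two edge
slices, and +z as the shaft axis. Marks are the exact geometric
intersection with the indenter (endpoints on the adjacent intact
vertices). Optional noise is isotropic in-plane Gaussian jitter applied
after sampling, seeded; defaults are noise-free. Default sampling (0.5 mm
spacing, 0.1 mm step) is deliberately finer than clinical MRI so that
discretisation error is small against the closed forms; `clinical_spec()`
(3.3 mm / 0.31 mm, a realistic acquisition row) exercises the coarse
regime, where the volume tolerance widens to 20 %.

What the phantom does *not* emulate: MR intensities and segmentation error,
non-spherical condyle shape, cartilage, bone-bruise (non-cortical) lesions,
and defects near the contour seam (the generator rejects indent directions
whose defect would wrap across it). Passing phantom tests therefore
demonstrates correctness of the geometry pipeline, not robustness to
segmentation variability.

## Published-table arithmetic

The printed six-segment cohort table of a 50-knee clinical study ships in
`datasets.py` as input data. Its internal arithmetic is checked rather than
recomputed (the images are not public): segment sums against printed totals
carry ±0.15 (six values independently rounded to one decimal), single-value
comparisons ±0.05. Under the all-knees-averaging convention (zero
contributions included) the printed columns do sum to the printed totals;
this is the convention `summarize_cohort` implements. Known
irreconcilables, excluded from checking: the two contradictory SDs printed
for the affected area (99.6 mm² vs 0.1 cm²), the "percent of region"
column (not derivable from the printed affected/region values), and a
"68 % / 30.8 % of the weight-bearing area" statement with undefined
denominators. Cohort SDs use the n−1 denominator (unstated in the source;
standard for small samples) and are reported as missing for n = 1.

## Problem sizes

The test suite and acceptance script run phantoms of 31–61 slices with
0.1–0.4 mm in-plane steps (≈ 3 000–70 000 contour points) and K = 200
resampling — sizes at which every closed-form comparison is
discretisation-limited, chosen as the smallest grids whose sampling error
sits comfortably inside each stated tolerance.
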