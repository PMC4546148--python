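# notchmorph

Morphometry of the **lateral femoral notch sign** — the impaction fracture of
the lateral femoral condyle that accompanies rupture of the anterior cruciate
ligament (ACL). The toolkit is aimed at musculoskeletal imaging researchers
who quantify these defects from routine knee imaging:

- **Radiograph screening** (`radiograph`): the condylopatellar sulcus depth is
  measured by drawing a tangential line across the sulcus on the articular
  profile and taking the maximum perpendicular distance to the profile at its
  deepest point; a depth ≥ 1.5 mm constitutes the notch sign (intact knees
  average ≈ 0.5 mm).
- **Slice-wise defect geometry** (`slicegeom`): in each sagittal MRI
  segmentation the depressed interval is marked (or auto-detected from the
  contour's convex hull) and bridged with a spline through the flanking
  vertices, approximating the bone surface under normal anatomical
  conditions. Each bridged slice yields a defect depth and a gap
  cross-section area.
- **3D morphometry** (`morphometry3d`): stacked contours are resampled by arc
  length and strip-triangulated into an open surface. Reported per knee:
  antero-posterior length, medio-lateral width, depth *t*, primary (bridged)
  surface area *A*ₚ, concave (depressed) surface area *A*𝒸, volume
  *V* = ∫ *A*(x) d*x* (trapezoidal over slice positions), and
  *A*ₚ as a percentage of the whole-condyle surface.
- **Regional mapping** (`regions`): two parallel planes — through the
  trochlear notch (spanned by the femoral shaft axis and the
  posterior-points vector) and at 60 % of the notch→posterior distance —
  plus a 50 % medio-lateral split partition the surface into six segments
  (AI, AE, CI, CE, PI, PE); CI+CE form the weight-bearing area. Defect
  quantities are attributed per segment and the primary location is the
  segment with the largest affected area.
- **Cohort reporting** (`cohort`): screening (sulcus ≥ 1.5 mm and MRI
  confirmation), means/SDs, a six-segment mean table, and explicit
  internal-consistency checks (segment sums reproduce totals, unit pairings,
  percentage arithmetic).
- **Phantoms** (`phantom`): a spherical condyle indented by a second sphere.
  With condyle radius *R*, indenter radius *r* and depth *t*, the center
  distance is *d* = *R* + *r* − *t* and every reported quantity has a closed
  form (spherical caps 2π*ρh* and the sphere–sphere lens volume), so the
  whole pipeline is validated against analytic ground truth.

## Worked example

```python
from notchmorph import (PhantomSpec, generate_phantom, total_surface_area,
                        defect_metrics, build_partition, assign_regions,
                        classify_primary_location)
from notchmorph.morphometry3d import bridge_marked_slices

slices, truth = generate_phantom(PhantomSpec())   # R=20, r=10, t=3 mm
total = total_surface_area(slices)
m = defect_metrics(bridge_marked_slices(slices), total)
print(f"total {total.total_area_cm2:.2f} cm2  depth {m.depth_mm:.2f} mm  "
      f"volume {m.volume_mm3:.1f} mm3  primary {m.primary_area_cm2*100:.1f} mm2")
print(f"closed forms: depth {truth.defect_depth_mm:.2f}  volume "
      f"{truth.volume_mm3:.1f}  primary {truth.primary_area_mm2:.1f}")
```

prints

```
total 37.66 cm2  depth 2.98 mm  volume 177.8 mm3  primary 119.3 mm2
closed forms: depth 3.00  volume 178.8  primary 118.7
```

i.e. the measured pipeline recovers the analytic depth within 0.1 mm and the
areas/volume within 1 % at fine sampling. The same objects feed the regional
partition (`build_partition` / `assign_regions`) and the cohort summary.

The command-line interface mirrors the library:

```sh
notchmorph phantom --out knee.json --seed 7     # synthetic segmentation + truth CSV
notchmorph xray profile.csv                     # sulcus depth + notch sign
notchmorph measure knee.json                    # per-knee metrics row
notchmorph regions knee.json                    # six-segment table
notchmorph report knee*.json --out-dir results  # cohort summary + checks
```

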