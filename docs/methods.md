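# Methods

This note records the models, numerical choices and limitations behind
crownct, in the package's own terms.  Coordinates are `(z, y, x)` with the
apicobasal axis along `z`; voxel centres sit at `(index + 0.5) ×
voxel size`; all lengths are millimetres.

## Synthetic crown phantoms

The phantom generator stands in for unavailable raw scans.  It emulates a
bulbous, four-crested herbivore crown as an implicit solid:

* **Dentine core.**  A superellipse cross-section `(|x|/a)^p + (|y|/b)^p ≤ 1`
  (exponent `p = 3` puts four crests toward the diagonals) whose half-axes
  taper as `(1 − u)^0.8` with height fraction `u`, from the basal
  half-widths to the cusp.  Defaults place a 2.2 × 1.6 × 2.6 mm crown in a
  128³ grid of 26 µm voxels — a scaled-down crown with the full-size
  enamel thickness profile, so thickness statistics are directly
  comparable with measured specimens while the default grid stays small.
* **Pulp cavity.**  The core scaled by `pulp_scale` (default 0.66) about
  the basal centre, inheriting the pyramid-with-crests shape and opening
  through the crown base, as in the specimen it emulates.
* **Enamel cap.**  All voxels outside the core whose Euclidean distance to
  it (computed by exact distance transform) is at most a thickness field
  `T(θ, u)`: basal thickness 0.20 mm over the lower crown, blending
  smoothly to 0.10 mm at the apex above `u = 0.55`, plus apicobasal ridges
  `amplitude · (1 − u) · max(0, cos(n·θ))^8` (default amplitude 0.25 mm,
  `n = 8`), giving ridge crests up to ≈ 0.45 mm that fade toward the cusp.
  The plateau below the apex blend makes 0.20 mm the modal thickness by
  construction.
* **Basal closure.**  An optional `basal_pulp_overhang_mm` lets dentine
  and cavity extend below the ventralmost enamel.  Cavity voxels below
  that plane are matrix infill: they sample pulp-like attenuation but are
  ground-truth background, which is exactly what the segmentation's
  base-closure step must recover.

**Attenuation sampling.**  Published per-tissue windows and modal peaks
drive a truncated normal per tissue (sd = window width / 6 — a free
choice, since only the windows and peak locations are published, not the
within-window shape).  In neutron mode the windows are additionally
truncated at the segmentation boundaries (enamel–dentine 1.0399,
dentine–pulp 0.9185) so a noiseless phantom is exactly separable; the
published windows themselves overlap those boundaries slightly (dentine
low 1.0254, pulp high 0.9243), and the `AttenuationModel` retains the
published values verbatim.  In X-ray mode the windows overlap heavily and
no boundary exists — deliberately, to reproduce the failure mode.
Gaussian noise (default sd 0.02) is added everywhere, then a speckle
fraction (default 1%) of voxels is replaced by uniform draws on
[0, 2 × highest window], giving the despeckle filter a defined target.
The declared 16-bit quantization range runs from −0.25 × to 2 × the
highest window value; the negative headroom keeps noisy background voxels
off the clipping floor.

**Calibration.**  `calibrate_spec_to_volume_ratios` tunes `pulp_scale`
(pulp/dentine goes as its cube) and a global thickness multiplier
(enamel/dentine is nearly linear in it) by alternating one-dimensional
updates against voxelized ground truth; it converges to the requested
volume ratios within ~1% in a few iterations.

What the phantom does **not** emulate: beam hardening, ring artefacts,
partial-volume blur at boundaries, spatially varying mineralisation, or
the real specimen's exact morphology.  Passing tests therefore demonstrate
correctness of the algorithms under the stated attenuation model, not
robustness to every artefact of real reconstructions.

## Reconstruction-side filters

Both filters work on the 6-connected neighbourhood; neighbours outside the
grid are omitted rather than padded.  Grey-value parameters are expressed
in 16-bit grey levels of the volume's declared range, mirroring
reconstruction software conventions.

* **Despeckle** replaces aberrant voxels by the mean of their non-aberrant
  6-neighbours, in a single pass.  Aberrance requires both
  `|v − median₂₇| > k · (MAD₂₇ + 1 grey level)` (k = 6) **and** that the
  voxel be a strict extremum of its 6-neighbourhood.  The extremum
  condition is essential: without it, tissue-boundary voxels (whose
  neighbourhood median and MAD are dominated by the adjacent tissue) are
  flagged and smeared with cross-tissue means, and the count of
  out-of-window voxels on a speckled phantom *rises* instead of falling.
* **Edge-stopping diffusion** is the explicit scheme
  `v ← v + λ Σ_q (n − v)` over the neighbours with `|n − v| ≤ stop
  criterion` (default 3327 grey levels ≈ 0.18 attenuation units of the
  phantom's range), `λ = 1/6`, five iterations.  The update is a convex
  combination, so the global value range never expands, and contrasts
  above the criterion are preserved exactly.  The exact update rule used
  by the original reconstruction software is not published; this scheme is
  declared in config and the tests assert only scheme-independent
  properties (identity on constants, range bounds, edge preservation).

## Segmentation protocol

1. Whole-tooth mask by a tooth-vs-background threshold (default 0.15,
   below the lowest tissue window), hole-filled, largest 26-component.
2. Mask voxels above the enamel–dentine boundary → dentine.  The
   remaining mask voxels are split spatially: within each horizontal
   slice, voxels enclosed by the dentine ring are interior; the rest form
   the outer shell → enamel.  A purely value-based split cannot work —
   the enamel window (0.52–1.04) straddles the dentine–pulp boundary —
   and the slice-wise ring test stays valid where the pulp cavity opens
   through the crown base.
3. Interior voxels below the dentine–pulp boundary → pulp; interior
   voxels at or above it are boundary dentine.
4. Island reabsorption: per tissue, 26-connected components smaller than
   half the tissue's largest component (or smaller than 8 voxels
   outright) are relabelled to the 6-adjacent majority label, iterated to
   a fixed point.  This replaces interactive island editing with a
   deterministic rule.
5. Base closure: pulp voxels below the horizontal plane through the
   ventralmost enamel voxel are relabelled background (matrix infill, not
   cavity); dentine-labelled voxels near the plane whose attenuation
   falls inside the enamel window and which touch existing enamel are
   annexed to the basal enamel ring.

Models without a separating enamel–dentine threshold (X-ray windows)
raise `NonSeparableError` before any voxel is touched.

## Thickness measurement

Surfaces come from marching cubes at the 0.5 level of the tissue
indicator after a 1-voxel Gaussian interpolation of the indicator (the
level set is clamped to stay inside the voxelized tissue).  This is
sub-voxel interpolation of the *extraction*, not mesh smoothing: raw
binary isosurfaces carry flat caps and 45° facets whose geometry biases
both areas (+5%) and ray lengths (beyond one voxel at sphere poles); with
the interpolated indicator, mesh areas of voxelized spheres match 4πr²
within 0.3% and per-element thickness errors stay below one voxel.
Faces are classified outer/inner by sampling the label map a fraction of
a voxel to each side; outward normals follow from the same test.

Thickness per outer element: cast a ray from the element centroid along
the inward normal (normals first averaged over ~3 median edge lengths —
the one concession to facet noise; geometry is untouched); take the first
intersection with the inner surface among the 64 nearest inner-triangle
candidates, accepting only triangles whose outward normal opposes the ray
within a 90° cone; if the ray misses, fall back to the distance of the
nearest opposing inner triangle; otherwise the element is flagged
undefined (never zero-filled).  Ray–triangle intersection is vectorized
Möller–Trumbore; candidate search uses a k-d tree.  The measurement is
scale-equivariant and, on analytic concentric and eccentric spherical
shells, agrees with the closed-form thickness within one voxel per
element — the anchor that fixes all free constants above.  Direction
defaults to outer→inner; the flag exists because the reference
implementation's convention is unknown.

Histograms count surface *elements* per bin (not area), with bin edges at
integer multiples of the bin width (default 0.026 mm, one voxel) and ties
resolved to the lower bin.

## Fracture mechanics

Margin-crack load `F = c · K_c · √t · R`, evaluated in SI after
converting mm and MPa·m^0.5 inputs; radial-crack load is exactly half.
The shape-coefficient curve `c(h/R)` is piecewise linear through the
published anchors (0.5 → 6–8, 1.9 → 17, 2.1 → 36, 2.32 → 42, 3.0 → 50–55),
clamped to the bunodont band below h/R = 0.5 and to the hypsodont plateau
above 3.0; both band edges are monotone by construction and the anchors
are exposed in config.  Interval propagation evaluates all 16 corners of
the (c, K_c, t, R) box; monotonicity makes the all-low/all-high corners
the exact extrema, which the code asserts on every call.  Bite-force
extrapolation multiplies a reference taxon's measured bite force by the
ratio of critical-load endpoints; when target equals reference the
prediction collapses to the measured value, a property under test.

Reports round forces to the nearest newton and ratios to one decimal;
internal computation is unrounded.

## Known limitations

* The phantom's crown is generic; it calibrates volumes and thickness
  statistics, not specimen-specific morphology.
* Partial-volume effects at tissue boundaries are not modelled, so
  segmentation accuracy on real scans will be bounded by boundary blur
  that the phantom lacks.
* The nearest-opposing fallback uses centroid distances (error up to
  about one triangle radius); it applies only to elements whose ray
  misses, mostly along the open basal rim.
* The demo grid (128³) uses a scaled-down crown; reproducing a full-size
  4.7 × 3.3 × 4.2 mm crown at 26 µm requires a ~216 × 162 × 170 grid and
  proportionally more runtime, with no code changes.
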