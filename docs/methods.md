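# Methods

This note documents the models behind `graftvol`: what is simulated, the
algorithmic choices where the design was genuinely open, the parameters
that matter, and the limits of what the synthetic validation shows.

## Coordinate and voxel conventions

Grids are indexed `data[x, y, z]`, isotropic spacing (default 0.25 mm),
voxel centers at `origin + index * spacing`. A voxel belongs to an
analytic shape iff its **center** lies inside the surface; axial extents
are half-open intervals, and generators place voxel centers at
half-spacing offsets from the analytic reference planes so no center ever
sits exactly on a boundary. These two rules make every voxel count
reproducible by brute-force enumeration, which is how the generators are
tested.

Axis 0 is the slice-stack axis. All phantoms are generated with the
graft/implant principal axis along it — the bench models sit on tilting
plates that rotate that axis by 15–35° (`mount_at_angle`, nearest-neighbor
label resampling; graft voxel counts change by ≲ 0.3 %), while the
ex-vivo-style bone blocks are scanned axis-aligned. Which anatomical plane
the stack corresponds to is a labeling question only; the interpolation
always runs along a single user-chosen axis, with no multi-axis fusion.

## Phantoms

* **R** — implant (4.1 × 10 mm) inside an annular graft. The outer radius
  is solved analytically so the designed annulus volume is exactly
  928.44 mm³; the voxelized truth lands within 1 %. A bone-like body ring
  surrounds the annulus so the graft has a material boundary on both sides.
* **S1 / S2** — curved-ridge grafts. The published bench models derive
  from clinical CBCT cases whose CAD is not available, so the generator
  reproduces *volume and topology class*, not exact shape: a seeded
  smooth radial modulation of an ellipsoid (deterministic per seed), a
  lateral spherical scoop for the concave S2, and an implant cylinder
  through the form. A uniform scale factor is bisected until the graft
  voxel volume is within 0.2 % of the target (954.77 / 404.82 mm³);
  failure beyond 2 % raises a convergence error carrying the achieved
  volume. The validation protocol depends only on truth volume and
  convex-vs-concave class, which is why this stand-in is sufficient.
* **BD5-1.5 … BD6-3** — trephine defects of 5/6 mm diameter, 8 mm depth,
  grafted, in a bone block, with a parallel 3.3 mm implant 1.5/3 mm away
  (surface-to-surface). The VOI is the middle 5 mm (top 1 mm, bottom 2 mm
  excluded); its analytic truth is π r² · 5 mm = 98.17 / 141.37 mm³
  (98.13 / 141.30 when π is truncated to 3.14, the printed-control
  convention `control_volume_cylinder(..., pi_mode="paper_2dp")`
  reproduces with half-up rounding).

A fabrication-error budget (±0.24–0.4 %) is carried as metadata; surface
jitter emulating it is off by default and plays no role in the tests.

## CBCT artifact model

Streaks are modeled **geometrically**, not by polyenergetic projection and
reconstruction: in every stack slice whose plane crosses the implant,
`streak_count` angular lobes radiate from the implant cross-section
centroid with amplitude `streak_amplitude · cos(Nθ + φ_slice) ·
exp(−streak_decay · d)` (d = distance to the implant surface), plus a dark
band of width `dark_band_width` hugging the implant at 0.6 × the streak
amplitude. Base intensities are background 100, bone 400, graft 800,
implant 3000 (arbitrary units); bone gets a smooth trabecular texture and
the whole volume white noise. The rationale: the segmentation method
operates on reconstructed images, so only the corrupting effect on
boundary delineation matters for validating it. Scanner settings (kV, mA,
FOV) would only be metadata and are not modeled. No artifact-reduction
reconstruction is attempted — the method under test explicitly works on
the images as they are.

**Slice severity** is the fraction of graft-boundary voxels in a slice
that the *deterministic* artifact field pushes across the nominal graft
threshold (the bone/graft intensity midpoint). Computing it without the
noise term makes severities reproducible and monotone in the streak
amplitude. Slices whose plane misses the implant have severity 0.

Defaults (`streak_amplitude 600`, `decay 0.15 /mm`, `9` lobes, `band
1 mm`, `noise σ 25`) were chosen so that streaks flip boundary voxels out
to a few millimetres from the implant — severities of roughly 0.05–0.3 on
implant-crossing slices — enough that an every-slice tracer is visibly
degraded while the scan remains segmentable. No published quantification
of artifact intensity exists for this protocol; these are this package's
study conditions.

## Emulated raters

A traced contour is the true boundary displaced radially by a smooth
correlated field (Gaussian-filtered white noise, correlation length
`smoothing_scale` = 1 mm) with mean `bias_per_severity · severity` and SD
`jitter_sigma · severity`. Defaults: bias −0.5 mm per unit severity
(under-tracing near artifacts — the empirically observed direction of
manual error in this protocol is negative), jitter 0.4 mm. A zero model,
or severity zero, reproduces the truth bit-exactly. Displacement is
applied through the sub-voxel signed distance transform, so shifts below
half a voxel act only where the smooth field crosses the quantization
threshold — mimicking how small perceptual bias shows up patchily in a
discrete tracing.

The two arms differ only in what they trace:

* **MCI arm** — input slices are selected greedily: from the last
  selected slice, take the minimum-severity slice within the next
  `max_gap` (default 5) slices, ties to the farthest candidate (uniform
  severities thus give a regular stride); both ends of the graft extent
  are always included and no gap exceeds `max_gap`. Input slices are
  traced at severity 0 — the method's premise is that the chosen slices
  are effectively artifact-free. Repeat-to-repeat variation comes from a
  ±1-index jitter of the interior selections (with a repair pass that
  restores the gap guarantee).
* **Manual arm** — every slice of the graft extent is traced at its true
  severity; repeats vary through the stochastic tracing field.

Each protocol repeat runs two raters with derived seeds and records the
across-rater mean volume; volumes, not masks, are averaged.

## The interpolation core

Open choices and how they were fixed:

* *Similarity*: "equally similar to both inputs" is operationalized as
  the argmax of min(Jaccard-to-A, Jaccard-to-B), ties to the lower
  sequence index. Jaccard sits behind a single `_jaccard` function should
  another metric ever be wanted.
* *Transition chain*: conditional dilation of the aligned intersection,
  run toward A and toward B separately; the sequence element at parameter
  t is `shrink_A(t) ∪ grow_B(t)`, so the chain starts exactly at A and
  ends exactly at B and every element is sandwiched between aligned
  intersection and union.
* *Structuring element*: transition chains alternate 4- and 8-connected
  3×3 dilations. Pure 8-connected growth turns disks into squares and
  demonstrably biases the median shape small (a 4 px → 8 px disk pair
  yields a ~5 px median instead of ~6 px); the alternation grows octagons,
  the standard discrete approximation of Euclidean growth, and restores
  the expected geometric behavior. Erosion of vanishing regions keeps the
  3×3 square; region labelling is 4-connected with scan-order numbering.
* *Correspondence*: regions pair iff they overlap in-plane; bipartite
  connected components form the groups, so one-to-many branching and
  many-to-many merges are handled uniformly. (A centroid-alignment rule
  was considered and rejected: aligning candidate pairs before testing
  overlap matches *any* two non-empty regions, which would make
  disappearing regions unrepresentable.)
* *Alignment*: the two group masks are translated so their centroids meet
  at the midpoint, integer shifts rounded toward zero.
* *Empty aligned intersection*: the chains grow from each shape's own
  innermost pixel instead — documented fallback, no exception; the
  endpoint elements then carry the partner's seed pixel.
* *Disappearing regions*: eroded toward extinction linearly across the
  gap (never fully gone on interior slices).
* *Gap guarantee*: a gap wider than `max_gap` raises a distorted-input
  error rather than extrapolating — if no usable slice exists within the
  window, the method's premise is violated and it should refuse.

Interpolation is bit-deterministic; annotated slices pass through
unchanged; interpolation between consecutive annotated slices only.

## Statistics and surfaces

CV uses the sample (n−1) SD — the convention for repeatability studies;
with five repeats the choice is material, so `ddof` is configurable.
Reports assert their own invariants (CV = 100·SD/mean, error identities,
min ≤ mean ≤ max) on construction. Angle-merged tables pool the per-angle
repeat lists; *repeatability* is additionally reported per scan (the CV of
the five repeats of one mounted scan), because merged CVs absorb the
systematic between-angle differences of the tilt + interpolation pipeline
(up to ~1.4 % for the annulus) that per-scan repeatability should not be
charged with. Routine significance testing (repeated-measures ANOVA,
paired t-tests) is out of scope; the per-angle means needed for any such
external test are exposed.

Surfaces are marching-cubes iso-surfaces at level 0.5 of the padded
binary mask, in physical mm. Registration is a landmark Kabsch fit
(rotation + translation, no scaling; collinear landmarks rejected);
since phantoms and segmentations share one frame, the default fiducials
(implant-axis endpoints, graft bounding-box corners) recover the identity,
and registration is exercised by perturbation tests. Deviation maps send
every test vertex to its exact nearest point on the reference triangles
(KD-tree over triangle centroids for candidates, then vectorized
point-triangle projection), signed by the nearest triangle's outward
normal. STL export is binary, millimetre units.

## Problem sizes and determinism

The validation battery runs all seven phantoms at the full 0.25 mm study
spacing on tightly cropped grids (≈ 50–90 voxels per side), five repeats ×
two raters, bench models at three angles — about 130 complete MCI
reconstructions — in well under a minute on one CPU. Every random draw
(artifact phases and noise, rater fields, slice jitter, repeat seeds)
derives from one master seed through `numpy` seed sequences; identical
seeds reproduce every volume bit-exactly.

## What the synthetic validation does and does not show

The generator reproduces the *structure* of the bench protocol — truth
volumes, geometry classes, artifact-corrupted boundaries, two raters ×
five repeats, VOI rules — so the suite demonstrates that the MCI
implementation is accurate and repeatable under those conditions and
degrades more gracefully than an every-slice tracer biased by artifacts.
It does not reproduce physical CBCT physics (beam hardening, scatter,
reconstruction kernels), real trabecular texture, graft-particle
granularity, blood or soft tissue, or human perceptual behavior; the
manual-arm error magnitudes follow from the rater model's parameters, not
from human data. The axis-aligned defect cylinders interpolate exactly by
construction (constant cross-sections), so their near-zero errors
reflect the easiest case of the method, as cylinder phantoms do on the
bench; the tilted bench models carry the informative interpolation error.
The method remains unsuitable for severely distorted stacks where no
usable slice exists within the gap window — the implementation refuses
rather than guesses.
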