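# graftvol

Semiautomatic volumetry of bone grafts around dental implants, validated
on synthetic CBCT phantoms.

## The problem

After guided bone regeneration (GBR) with simultaneous implant placement,
clinicians want to follow the grafted bone volume over time from cone-beam
CT (CBCT). Manual slice-by-slice tracing is the accepted reference, but it
is slow and — worse — titanium implants throw bright/dark streak artifacts
across exactly the slices that matter, so a human tracing every slice
accumulates error where the boundary is least visible.

The semiautomatic alternative implemented here is **morphological contour
interpolation (MCI)**: the operator traces the graft perimeter only on
slices with no or few artifacts (never more than `max_gap = 5` slices
apart), and morphology fills everything in between. For each pair of
consecutive input contours *A*, *B* (after translating both so their
centroids meet halfway), a *transition sequence* is built by conditional
dilation of *A* ∩ *B* constrained inside *A* ∪ *B* — a chain of shapes
gradually transforming one contour into the other. The element equally
similar to both endpoints,

&nbsp;&nbsp;&nbsp;&nbsp;argmax<sub>k</sub> min( J(T<sub>k</sub>, A), J(T<sub>k</sub>, B) ),&nbsp;&nbsp;&nbsp;J = Jaccard index,

becomes the middle slice, and the gap is filled by recursive binary
subdivision. Branching regions are handled through overlap correspondence
groups; regions with no partner erode toward extinction across the gap.

Because no deposited scans exist for this protocol, the package also
generates the complete validation world at desk scale:

* **phantoms** — seven truth geometries with known volumes: a concentric
  cylinder `R` (annular graft, 928.44 mm³), two curved alveolar-ridge
  forms `S1`/`S2` (954.77 / 404.82 mm³, `S2` with a lateral concavity),
  and four grafted trephine defects `BD{5,6}-{1.5,3}` (5/6 mm diameter,
  8 mm deep, implant 1.5/3 mm away; the volume of interest is the middle
  5 mm), all at 0.25 mm isotropic voxels, bench models mounted at
  15°/25°/35°;
* **cbct_sim** — label-to-intensity mapping plus geometric metal-streak
  and dark-band artifacts with per-slice severity scores;
* **annotation** — emulated raters: artifact-aware sparse input tracing
  for the MCI arm, and a severity-biased every-slice tracer for the
  manual arm (two raters × five repeats, across-rater means recorded);
* **mci_core** — the interpolation itself;
* **volumetrics** — volumes in a VOI, coefficient of variation,
  systematic and relative systematic error, per-angle pooling;
* **surface_eval** — marching-cubes surfaces, point-based rigid
  registration, signed surface-deviation maps, STL export.

## Worked example

```python
from graftvol.battery import run_battery
from graftvol.volumetrics import reports_to_frame

results = run_battery(seed=1)  # all seven phantoms, both arms
print(reports_to_frame(
    [c.reports[m] for c in results for m in ("mci", "manual")]
).to_string(index=False))
```

```
phantom method  n   mean   sd    min    max  cv_pct  control  systematic_error  relative_systematic_error_pct
      R    mci 15 928.64 9.35 913.11 940.31    1.01   928.44              0.20                           0.02
      R manual 15 842.99 3.35 838.08 848.05    0.40   928.44            -85.45                          -9.20
     S1    mci 15 952.84 3.02 948.72 959.55    0.32   955.67             -2.84                          -0.30
     S1 manual 15 912.29 1.56 909.08 914.65    0.17   955.67            -43.38                          -4.54
     S2    mci 15 404.90 5.60 394.99 415.58    1.38   404.36              0.54                           0.13
     S2 manual 15 365.01 1.99 361.61 368.94    0.55   404.36            -39.35                          -9.73
BD5-1.5    mci  5  98.75 0.00  98.75  98.75    0.00    98.75              0.00                           0.00
BD5-1.5 manual  5  88.90 0.32  88.51  89.33    0.36    98.75             -9.85                          -9.97
  BD5-3    mci  5  98.75 0.00  98.75  98.75    0.00    98.75              0.00                           0.00
  BD5-3 manual  5  95.17 0.57  94.27  95.80    0.60    98.75             -3.58                          -3.63
BD6-1.5    mci  5 140.00 0.00 140.00 140.00    0.00   140.00              0.00                           0.00
BD6-1.5 manual  5 131.34 0.63 130.70 132.10    0.48   140.00             -8.66                          -6.19
  BD6-3    mci  5 140.00 0.00 140.00 140.00    0.00   140.00              0.00                           0.00
  BD6-3 manual  5 135.09 0.38 134.48 135.45    0.28   140.00             -4.91                          -3.51
```

Each row pools the five repeat volumes (each the mean of two emulated
raters; bench models additionally pooled over the three mounting angles,
hence n = 15). Reading it: the MCI arm stays within a fraction of a
percent of the truth everywhere and is *exact* on the axis-aligned defect
cylinders (constant circular cross-sections interpolate perfectly), while
the artifact-biased manual arm under-traces every phantom — its
systematic errors are all negative and largest where streaks hit the
graft boundary hardest (the concave `S2`, the annulus `R`). Per-scan
repeatability of the MCI arm (CV of the five repeats of one scan) stays
below 1 %.

The same pattern shows up on surfaces:

```python
from graftvol.battery import surface_comparison
dev = surface_comparison("S2", seed=1)
print(dev["mci"].mean_abs, dev["manual"].mean_abs)   # 0.054 vs 0.085 mm
```

The command line mirrors the library:

```bash
graftvol generate --model BD6-1.5 --out work/
graftvol simulate --labels work/BD6-1.5_labels.nrrd --seed 1 --out work/
graftvol annotate --labels work/BD6-1.5_labels.nrrd --severities work/severities.csv --mode mci --out work/
graftvol interpolate --sparse work/sparse_annotations.nrrd --index-table work/slices.csv --out work/dense.nrrd
graftvol measure --mask work/dense.nrrd --voi 1 6
```

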