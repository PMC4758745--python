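# Methods

## Measurement model

A Scheimpflug exam is a stack of meridional lens sections: 8-bit grayscale
images whose pixel intensity is proportional to back-scattered light and
hence to local opacity. The pipeline computes two families of objective
metrics and relates each to the subjective LOCS III grade.

**Nuclear metric.** The nucleus is selected by a rotated elliptical ROI
(drawn per eye; the nucleus/cortex boundary varies between patients, so no
standard mask is possible). Nuclear cataracts opacify homogeneously from
the centre outward, so four meridians — 45°, 90°, 135° and 180° — suffice.
Per slice the maximum and arithmetic-mean intensity over ROI pixels are
retained; per eye the four per-slice maxima and means are averaged
(`agg_max`, `agg_mean`). Means are carried at full floating precision; a
separate 2-decimal display table mirrors clinical reporting.

**Cortical metric.** The cortex is an annular band delimited by closed
periodic cubic splines through ordered control points (an outer contour and
an inner contour just outside the nucleus; the band is the outer fill minus
the inner fill). Cortical cataracts progress asymmetrically, so the full
25-slice sweep is analysed per cataract eye; clear controls, whose cortex
is assumed homogeneous, use 4 slices (0/45/90/135°). The clear/opaque
cutoff is calibrated as the **maximum** cortical intensity over all pixels
of all control eyes; a pixel is opaque iff its intensity is **strictly
greater** than the cutoff. Strictness is deliberate: the cutoff is itself
attained by a clear eye, so every control eye scores exactly 0 % against
its own cohort's calibration — a property the test suite asserts.

Per area fraction *f* ∈ {1, 1/2, 1/3, 1/4} the peripheral sub-band of the
cortex is built per slice and opaque/total pixel counts are **pooled**
across the stack before forming the percentage. Pooling weights slices by
their cortex area, matching the "area of opaque cortex" reading of the
metric; a `aggregation="mean"` switch averages per-slice percentages
instead, for sensitivity analyses.

**Statistics.** Metric distributions are screened with a one-sample
Kolmogorov–Smirnov test against a normal fitted to the sample (reporting
gate only; the metrics are generally non-normal, so tables report
median [min–max] per grade, binned exactly at the recorded grades).
Agreement with the LOCS grade uses Spearman rank correlation with
average-rank ties; the two-sided p-value uses the t approximation for
n > 10 and exact permutation enumeration for n ≤ 10. An OLS tendency line
of metric on grade is reported descriptively. Eyes, not patients, are the
unit of analysis; no within-patient clustering correction is applied.

## Geometry conventions and numerics

* Coordinates are 0-based, x = column, y = row, origin top-left; angles
  counter-clockwise in degrees. A pixel belongs to a region iff its centre
  does; the ellipse inequality carries a 1e-12 slack so boundary pixels
  classify identically under rotations whose sines/cosines are not exact in
  floating point.
* Contours are sampled at ≥ 16 points per segment before polygon filling;
  a sampled curve that encloses less than half a pixel of area (e.g.
  collinear control points) or self-intersects is rejected. An
  interpolating periodic cubic through few, sharply-turning control points
  bulges well outside the control polygon (4 square corners yield a
  near-circumscribed circle, ~1.5× the square's area); contours should be
  specified with enough points that the spline tracks the intended
  boundary, as the 20-point phantom contours do.
* **Peripheral depth bands.** "Half/third/quarter of the cortex from its
  periphery" is defined by normalized radial *depth*, not by area: along
  the ray from the band centroid, depth = (r_outer − r)/(r_outer − r_inner)
  with r_inner/r_outer the band's radial extents at that angle; the band
  keeps depth ≤ f. Concentric sub-bands share the outer boundary, which is
  the faithful reading of periphery-in progression. Extents are estimated
  on 1° angular bins; since one degree of arc is thinner than one pixel at
  radii under ~57 px, each bin's extents are taken over the circular 3-bin
  window centred on it (min of inner, max of outer), guaranteeing more than
  two pixels of arc coverage. Radially degenerate rays keep their pixel at
  every fraction; fraction 1 returns the input mask exactly, so the bands
  nest monotonically. Depth is only ever evaluated at member pixels, whose
  bins are non-empty by construction, so no imputation for empty bins is
  needed.
* Reflex-excluded pixels are removed before any statistic and appear in no
  numerator or denominator; exclusion is idempotent.
* Slice meridians are matched to the required set within ±1°. Meridian
  labels live in [0°, 180°]; 0° and 180° denote the same anatomical
  meridian imaged at either end of the rotation sweep.

## The phantom generator

`lensopacity.synthetic` renders what the analysis assumes about real
exams, with ground truth:

* **Geometry** — a 160×160 grid; nucleus ellipse (semi-axes 30/20 px) at
  the centre, a dark separating gap (inner scale 1.15), and a cortex band
  out to an outer ellipse (62/46 px) carrying a smooth two-harmonic
  per-angle perturbation (amplitude 4 %) so rasterized contours are ragged
  the way hand-drawn ROIs are.
* **Intensities** — background 3, nucleus base 8, cortex base a triangular
  radial profile in [10, 30] with a per-eye brightness factor in
  [0.85, 1.0]. Noise-free clear cortex therefore never exceeds the
  34-intensity clear ceiling, inside the published pooled clear-group
  range (min 4, median 25, max 34); the exact levels are otherwise free
  parameters, since no per-pixel distributions are published.
* **Nuclear severity** — a homogeneous intensity elevation of the whole
  nucleus (centre-out growth has reached the ROI uniformly). Cohort grid:
  6/14/26/44/60 intensity units, mapped by fixed monotone binning to
  grades 1–4.
* **Cortical severity** *s* ∈ [0, 1] — six bright spokes (elevation +70)
  whose radial extent covers depth ≤ *s* from the periphery and whose
  angular width scales as 0.4 + 0.6·*s*; spoke positions are jittered per
  slice (±4°) to emulate asymmetric progression. Grid:
  0.12/0.25/0.45/0.65/0.85 → grades 0.5–3. On noise-free phantoms the
  peripheral quarter band is consequently at least as opaque as the whole
  cortex — the generator's periphery-in construction, asserted as a
  generator property in the tests. Clinical cohorts show the opposite
  ordering (whole ≥ quarter), plausibly because real spokes taper rather
  than fill their angular sector to a sharp depth; the phantom does not
  emulate tapering.
* **Artifacts** — two saturated reflex blobs (radius 2 px, intensity 255)
  per slice, one in the cortex and one in the nucleus, recorded in truth
  masks and exported as exclusion contours (radius +1.6 px, so the
  exclusion strictly covers the blob). Additive Gaussian noise (default
  sd 2), rounded and clipped to [0, 255].
* **Acquisition** — cataract eyes get 25 slices at 7.5° steps covering
  0°–180° inclusive. A 7°/7.2° step cannot place slices on the analysed
  meridians (45/90/135/180 are not multiples of either), whereas the
  7.5° fencepost sweep contains them exactly while keeping 25 images per
  exam; this is the package's reading of a rotating 25-image acquisition.
  Controls get 4 slices at 0/45/90/135°.
* **Seeding** — per-eye seeds derive from the master seed via
  `SeedSequence([master, index])`; renders are bit-identical for a fixed
  seed.

**What passing tests show, and what they do not.** The phantoms share the
analysis' own geometric vocabulary (elliptical nucleus, spline-bounded
band, sector spokes), carry no shadows cast by eyelids or nose, no
refractive distortion of deeper structures, no mature cataracts, and their
severity is a designed scalar. Tests against them validate the
*measurement machinery* — masks, counts, calibration, pooling, rank
statistics — and the monotone link from designed severity to metric
(severity-recovery Spearman ρ ≈ 0.98 on the default cohort of 10 controls
plus 60 cataract eyes over 5 severity levels at noise sd 2). They do not
validate clinical accuracy on real eyes, which requires real graded
images.

## Default cohort and problem sizes

The default synthetic cohort (10 control / 30 nuclear / 30 cortical eyes,
160×160 slices, 25-slice stacks for cataract eyes) renders and analyses in
well under a minute on one CPU; mask rasterization is cached per eye since
ROIs are constant across an eye's stack. Brute-force oracle comparisons in
the tests run on grids of ≤ 70×70 pixels, where exhaustive per-pixel
recomputation is fast.

## Known limitations

* Cortex ROIs are consumed as parameters; automatic nucleus/cortex
  detection is out of scope.
* The device's native exam format is not parsed; slices enter as plain
  8-bit grayscale PNG/TIFF plus a YAML manifest.
* The exact-permutation Spearman p-value enumerates n! pairings and is
  limited to n ≤ 10 (larger samples use the t approximation).
* Control eyes carry only the 4-slice protocol and therefore only cortical
  metrics; nuclear descriptive tables cover the cataract cohort.
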