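# lensopacity

Objective grading of nuclear and cortical cataracts from Scheimpflug
lens-section images, with agreement statistics against the subjective
LOCS III clinical scale.

Rotating-Scheimpflug cameras photograph optical cross-sections ("slices")
of the crystalline lens; pixel intensity reflects back-scattered light and
hence opacity. `lensopacity` implements the measurement pipeline an
ophthalmic-imaging group would run on such slice stacks:

* **Nuclear opacity** — pixel intensities inside an elliptical region of
  interest (ROI) over the lens nucleus. For each of four meridians
  (45°, 90°, 135°, 180°) the maximum and mean intensity are retained,
  then averaged across meridians:
  `agg_max = (1/4) Σ max_i`, `agg_mean = (1/4) Σ mean_i`.
* **Cortical opacity** — the percent-opaque-pixel metric. A clear/opaque
  cutoff *T* is calibrated on a clear-lens control cohort as
  `T = max{ I(p) : p ∈ cortex pixels of all clear eyes }`,
  and an eye's cortical opacity is
  `% opaque = 100 · #{p : I(p) > T} / #{p in cortex ROI}`,
  with opaque/total counts pooled over the eye's 25-slice stack. Because
  cortical cataracts grow from the periphery inward, the metric is also
  reported on the peripheral **half / third / quarter** depth bands of the
  cortex ROI.
* **Agreement with LOCS III** — per-grade descriptive tables
  (median [min–max]), a Kolmogorov–Smirnov normality screen, and Spearman
  rank correlation ρ of each metric with the ordinal LOCS grade, plus an
  OLS tendency line.

ROIs enter as parameters (nucleus ellipse, cortex spline contours, reflex
exclusion contours) — there is no interactive drawing — and specular-reflex
pixels are excluded from every numerator and denominator. Because no image
data are published alongside the clinical summaries, the package ships a
seeded phantom generator (`lensopacity.synthetic`) that renders slice
stacks with known geometry, severity and artifacts, so the whole pipeline
is testable end to end.

## Worked example

Simulate a 30-eye cohort (6 clear controls, 12 nuclear, 12 cortical
cataract eyes) and run the full analysis:

```bash
lensopacity simulate --out runs/demo --seed 7 --n-control 6 --n-nuclear 12 --n-cortical 12
lensopacity run --manifest runs/demo/manifest.yaml --out runs/demo/results
```

The run prints `threshold: 36.0` — the calibrated cutoff, i.e. the
brightest cortex pixel found in the six noisy control eyes — and the
correlation table. Selected rows of `results/metrics_display.csv` (the
2-decimal display table; one row per eye):

```
eye_id,group,locs_grade,...,agg_max,agg_mean,pct_whole,pct_half,pct_third,pct_quarter,threshold,n_slices
ctrl000,control,0.00,...,,,0.00,0.00,0.00,0.00,36.00,4
nuc000,nuclear,1.00,...,21.00,13.98,,,,,36.00,25
nuc002,nuclear,3.00,...,41.25,33.99,,,,,36.00,25
cort000,cortical,0.50,...,,,1.58,2.76,3.90,5.06,36.00,25
cort002,cortical,2.00,...,,,7.94,13.83,14.59,14.15,36.00,25
```

Every control eye scores exactly 0 % opaque cortex — by construction the
threshold is attained (not exceeded) in clear tissue. Nuclear `agg_mean`
rises from ~14 at LOCS grade 1 to ~34 at grade 3, and the cortical
percent-opaque rises with grade. `results/correlations.csv` quantifies the
agreement; for this cohort:

```
cohort,metric,n,rho,p_value,slope,intercept
nuclear,agg_mean,12,0.966,3.3e-07,15.56,-5.53
cortical,pct_whole,18,0.990,5.8e-15,5.05,-0.57
```

`results/descriptives.csv` holds the median [min–max] per grade for every
metric (the clinical-table layout), e.g. `pct_whole` medians of
0.00 / 1.58 / 3.76 / 7.88 / 15.35 % for grades 0 / 0.5 / 1 / 2 / 3.

The same results are available programmatically:

```python
from lensopacity import render_cohort, analyse_cohort
from lensopacity.pipeline import eye_from_synthetic

eyes = render_cohort(n_control=6, n_nuclear=12, n_cortical=12, seed=7)
metrics, calibration, threshold = analyse_cohort([eye_from_synthetic(e) for e in eyes])
```

## Layout

| module | contents |
| --- | --- |
| `lensopacity.roi` | ellipse / spline-contour rasterization, reflex exclusion, peripheral depth bands |
| `lensopacity.metrics` | nuclear slice/eye metrics, threshold calibration, percent-opaque |
| `lensopacity.stats` | descriptive tables, KS screen, Spearman + tendency line |
| `lensopacity.synthetic` | seeded phantom eyes and cohorts with ground truth |
| `lensopacity.io` / `pipeline` / `cli` | PNG + YAML manifest formats, orchestration, `lensopacity` command |

See `docs/methods.md` for the measurement model, the phantom's assumptions
and the numerical choices.
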