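# Methods

## Speckle model

Stromal OCT speckle intensity is modelled by the Generalised Gamma (Stacy)
family with density

    f(x; a, v, p) = p x^{pv-1} exp(-(x/a)^p) / (a^{pv} Γ(v)),  x > 0,

scale `a` (intensity units, arbitrary for OCT) and shapes `v`, `p`. The
family nests the exponential (v = p = 1), gamma (p = 1), Weibull (v = 1) and
Rayleigh (v = 1, p = 2) laws. `a` tracks average backscattered power; the
ratio `v/p` ("scatter density") tracks the effective density of
sub-resolution scatterers. The Stacy family also admits p < 0; that branch
is excluded here — corneal estimates live well inside p > 0 (typical
cohort values: a ≈ 0.29, v ≈ 0.44, p ≈ 2.8, v/p ≈ 0.16).

All distribution functions are computed in log space. The CDF is the
regularised lower incomplete gamma function at `(x/a)^p` with shape `v`; the
quantile function inverts it with `gammaincinv`. Sampling uses the exact
transform X = a·G^{1/p} with G ~ Gamma(v, 1).

### Maximum-likelihood fitting

`fit_gg_mle` maximises the log-likelihood of the raw (unbinned) samples over
`(log a, log v, log p)` — the log-parametrisation enforces positivity
without a constrained solver — by L-BFGS-B from a small multi-start grid
p₀ ∈ {0.5, 1, 2, 3}. Each start is initialised by the method of moments on
Y = X^{p₀}, which is gamma distributed given p₀. The best local optimum is
kept. Numerical choices:

* data are internally rescaled by their median, which makes the estimate of
  `a` exactly scale-equivariant and conditions the optimisation;
* gradient-norm tolerance 1e-8 on the per-sample negative log-likelihood;
* samples equal to 0 (possible after integer quantisation of linear
  intensities) are dropped with a logged count — the GG support is (0, ∞) —
  and negative values are an error;
* at least 500 positive samples are required; the default stromal ROI
  supplies 112,500.

The fit reports the KS distance between the empirical CDF and the fitted CDF
as a goodness-of-fit summary. Histograms (default 20 bins, density
normalised, with a fitted-pdf overlay) are presentation only and never enter
the estimation.

## Image pipeline

Conventions: rows are axial (increasing into the eye), columns lateral,
coordinates 0-based; intensities linear. Log-compressed images are refused
rather than silently de-compressed, since compression destroys the speckle
statistics the model targets.

Layer segmentation smooths each A-scan with an axial Gaussian (σ = 2 px) and
takes the centred first difference. Per column, the epithelium surface is
the first local maximum of gradient magnitude above threshold, the
endothelium the last, and Bowman's layer the strongest gradient extremum in
a window 40–80 µm below the surface (the epithelial band is ~55 µm thick).
The threshold is 0.08 × the median over columns of the per-column peak
gradient magnitude: tying it to the image-wide edge strength is robust to
the heavy-tailed per-column speckle maxima, and being gradient-based it is
invariant to constant intensity offsets. Detected boundary curves are
smoothed across columns by a quadratic polynomial fit with iterated
MAD-based outlier rejection; over a ±1.8 mm half-width a circular anterior
arc deviates from a quadratic by well under one axial pixel, so no higher
order is needed.

The corneal apex is the column where the first difference of the smoothed
epithelium curve crosses zero from negative to non-negative (the axial
minimum); ties break toward the centre of the valid span, and a monotone
curve is an error.

The ROI is 450 columns centred on the apex and 250 rows starting a
configurable offset below Bowman's row *at the apex* (default 60 µm). The
offset must exceed the sag of the Bowman arc across the ROI half-width
(~40 µm at the default geometry), otherwise the axis-aligned rectangle would
clip the epithelial band at its corners; placement fails loudly if any ROI
column crosses Bowman's layer or the endothelium. An optional saturation
mask (drop pixels above a percentile, off by default) is available for real
acquisitions with specular reflections.

## Synthetic data

### Corneal phantom

`generate_bscan` renders a two-surface phantom on the acquisition raster
(1024 A-scans × 848 px by default): a circular anterior arc (default radius
7.75 mm) with apex at a configurable column, a parallel Bowman arc 55 µm
deeper, and an endothelium at CCT (default 552.75 µm). Pixels are Rayleigh
background (scale 0.012), a brighter Rayleigh epithelial band (scale 0.45),
and GG(a, v, p) stromal speckle; the endothelium is rendered as a plain
stroma-to-background step so the ground-truth boundary coincides with the
gradient extremum the detector looks for. Exact float boundary rows are
returned per column.

The pixel pitch is not dictated by the raster size alone; the defaults
(1.5 µm axial × 3.5 µm lateral) were chosen once so that (i) a 250-row ROI
of pure stroma fits under the arc with the default CCT, and (ii) the arc is
quadratic to sub-pixel accuracy across the raster. Phantom images are
written as 16-bit TIFF/PNG with quantisation factor 20,000 recorded in a
JSON sidecar alongside the pixel geometry.

What the phantom does *not* emulate: axial PSF blur and attenuation with
depth, refraction at the anterior surface, specular apex reflection, motion
artefacts, and spatial speckle correlation (pixels are i.i.d.). Passing
recovery tests on phantoms therefore demonstrates the correctness of the
segmentation/ROI/MLE chain under the assumed statistics, not robustness to
every artefact of clinical acquisitions.

### Synthetic cohort

`generate_cohort` draws biometry (CCT, CR, AL, ACD, WTW), age and GG
parameters as independent truncated normals and sets

    IOP_nc = 0.0248·CCT − 16.534·GG_a + 6.853 + ε,  ε ~ N(0, 1.13²) mmHg,
    IOP_c  = IOP_nc − 0.0248·(CCT − 550 µm).

Defaults: CCT 552.75 ± 27.89 µm [488, 612], CR 7.75 ± 0.25 mm, AL
23.29 ± 0.82 mm, ACD 3.28 ± 0.38 mm, WTW 11.99 ± 0.32 mm, age
44.66 ± 19.32 y [22, 78], GG_a 0.287 ± 0.035, GG_v 0.437 ± 0.029, GG_p
2.80 ± 0.27. The noise SD 1.13 mmHg makes the structural model explain
~39 % of the IOP_nc variance at these marginals (signal variance
0.0248²·27.89² + 16.534²·0.035² ≈ 0.81 mmHg²).

Notes and deliberate simplifications:

* Truncation to the plausible min–max ranges uses rejection sampling; the
  parent normal of each variable is calibrated (via the truncated-normal
  moment equations) so the *truncated* law matches the target mean and SD.
  The age SD target (19.32 y) exceeds what any truncated normal on [22, 78]
  can deliver (the near-uniform bound is ≈ 16 y); the generator keeps the
  age mean exact and delivers the maximum attainable SD (~15.6 y), logging a
  warning. Real recruitment-age distributions are wider-tailed than a
  truncated normal.
* Variables are independent apart from the structural IOP link. Real
  biometric variables are weakly cross-correlated; the pipeline's tests
  only require the stated structure, and the independence assumption is a
  stand-in, not a claim about real cohorts.
* The device's proprietary CCT-correction table is not public; IOP_c uses a
  documented linear stand-in anchored at 550 µm. Its default slope equals
  the generative CCT coefficient, making the corrected pressure
  CCT-independent — the qualitative behaviour a thickness correction aims
  for. Real corrected IOP is consumed as data, never recomputed.

## Cohort statistics

* **Simple regression** — OLS via statsmodels; the p-value is the F test of
  the slope; the 95 % band is the pointwise confidence interval of the mean
  response, narrowest at the predictor mean.
* **Sample size** — n = σ²·(t(1−α, N−2) + t(1−β, N−2))²/(Δµ)², with
  one-sided t-quantile arguments as conventionally printed for this formula
  (a two-sided version would use 1−α/2); returned as a real with a ceiling
  variant. At σ = Δµ, α = 0.05, β = 0.01, N = 56 it gives 16.6.
* **Median split** — the split point is the median of all values (even n:
  mean of the two middle order statistics); records exactly at the median
  join the lower group with a logged count.
* **Group comparison** — two-sided Wilcoxon rank-sum (Mann–Whitney U) with
  normal approximation and tie correction, read as the two-independent-
  sample test since the groups are different subjects; plus mean ± SD per
  group.
* **Density contrast** — a two-sample KS test needs samples, so each group's
  mean GG parameter vector is converted to m deterministic pseudo-
  observations at the equispaced mid-quantiles (i + ½)/m (default m = 28,
  the group size); both m and the construction are configurable and logged.
  The p-value uses scipy's exact small-sample method.
* **Forward stepwise** — greedy entry by smallest partial-F p-value below
  α_enter (default 0.05; the threshold is a package choice), ties broken by
  larger R² then name order; collinear additions are skipped with a
  warning; selection stops early when the current fit is numerically perfect
  (SSE ≤ 1e-10·SST), where further partial-F p-values are meaningless. The
  final model is refit on the selected set.
* **Multiple testing** — none is applied; results are reported per
  parameter, as is conventional for exploratory cohorts of this size. Users
  comparing many parameters should adjust externally.

`cohort_analysis` orchestrates the full battery (all macro/micro regressions
against both IOP variants, speckle-vs-CCT cross-checks, median split, group
contrasts, density contrast, stepwise model) and emits a machine-readable
report plus figure-data CSVs.

## Problem sizes and reproducibility

Tests and the acceptance script use: 10⁵ draws for MLE recovery (5 %
tolerance), 2,000 draws against a 30³ brute-force likelihood grid, 20
full-raster phantoms for segmentation accuracy, 100 reduced-raster phantoms
for the layer-ordering property, 1,000 null regressions at n = 56 for type-I
calibration, one n = 5,000 cohort for coefficient recovery and 200 n = 56
cohorts for the selection-rate estimate. All randomness funnels through
seeded `numpy.random.Generator` instances; CLI runs write a manifest
(config hash, seed, versions) and identical configurations reproduce
byte-identical outputs.

## Known limitations

* Speckle is modelled statistically; no wave-optics simulation, no spatial
  correlation, no depth-dependent attenuation.
* Segmentation assumes a single cornea-like structure with three detectable
  axial edges; it is not a general anterior-segment segmenter.
* The intensity scale `a` is instrument-relative ("a.u."); absolute
  comparability across devices is not claimed.
* The independence of biometric variables and the linear IOP-correction
  stand-in are generator conveniences, not clinical claims.
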