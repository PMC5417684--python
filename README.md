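# octspeckle

Corneal OCT speckle statistics and their influence on noncontact tonometry.

Intraocular pressure (IOP) screened by air-puff (noncontact) tonometry is
biased by the cornea the instrument pushes against. The macro-structure —
central corneal thickness (CCT), curvature, and the rest of the ocular
biometry — is routinely measured and partially corrected for, but the
*micro*-structure (collagen fibril organisation, keratocyte density) also
stiffens the cornea and is invisible to biometry. The speckle pattern of an
anterior-segment OCT B-scan carries exactly that sub-resolution information:
the intensity statistics of linear (not log-compressed) stromal speckle
change with scatterer organisation.

`octspeckle` is a tested, reusable implementation of this analysis chain for
researchers in ocular biomechanics and quantitative OCT:

1. **Speckle model** — the stromal intensity `x` is modelled by the
   three-parameter Generalised Gamma (Stacy) law

   ```
   f(x; a, v, p) = p x^{pv-1} exp(-(x/a)^p) / (a^{pv} Γ(v)),   a, v, p > 0
   ```

   with scale `a` (average backscattered power, arbitrary units) and shapes
   `v`, `p`; the ratio `v/p` tracks scatterer density. Parameters are
   estimated from raw ROI pixels by maximum likelihood (`fit_gg_mle`), never
   from binned data.
2. **Image pipeline** — B-scans (TIFF/PNG/CSV) are segmented by axial edge
   detection into epithelium, Bowman's layer and endothelium; the corneal
   apex is the null of the epithelium curve's derivative; a fixed 250 × 450 px
   region of interest is placed in the stroma below Bowman's layer and its
   raw intensities feed the speckle model.
3. **Cohort statistics** — per-subject tables (columns `AL, CCT, ACD, CR,
   WTW, IOP_c, IOP_nc, GG_v, GG_a, GG_p, age`) are analysed with simple
   regressions (R², F-test, 95 % confidence bands), a median split on IOP
   with Wilcoxon rank-sum contrasts, a two-sample Kolmogorov–Smirnov contrast
   of the group-mean GG densities, the t-based sample-size formula, and
   forward stepwise least squares producing a structural IOP model of the
   form `IOP_nc = β₁·CCT + β₂·GG_a + β₀`.
4. **Synthetic data** — a corneal phantom generator (circular anterior arc,
   GG stromal speckle, ground-truth boundaries) and a cohort generator with
   configurable marginals and a built-in structural IOP model make every
   stage testable without clinical data.

## Worked example

Simulate a phantom B-scan, fit the speckle model end to end, then simulate
and analyse a 56-subject cohort:

```
$ octspeckle simulate-bscan --seed 5 --out phantom/
wrote phantom/phantom.tif

$ octspeckle fit-speckle phantom/phantom.tif --out fit/
phantom: a=0.288 v=0.4325 p=2.819 v/p=0.1534 ks=0.001588 (n=112497)

$ octspeckle simulate-cohort --seed 2 --out cohort/
wrote cohort/cohort.csv and cohort/cohort.xlsx

$ octspeckle analyze-cohort cohort/cohort.csv --out report/
n=56 IOP_nc median=15.97 mmHg
stepwise: IOP_nc = -16.24*GG_a +0.01928*CCT +9.933 (R^2=0.451)
report written to report
```

Reading the output: the phantom's stroma was generated with GG parameters
(a, v, p) = (0.287, 0.437, 2.80); the blind pipeline — segment, find apex,
place ROI, extract 250 × 450 linear intensities, maximum likelihood —
recovers them within ~1 %, with a KS goodness-of-fit distance of 0.0016.
The synthetic cohort was generated with the structural model
`IOP_nc = 0.0248·CCT − 16.534·GG_a + 6.853 + ε`; at n = 56 the stepwise
selector finds exactly {CCT, GG_a} and estimates coefficients within
sampling error of the generative ones. `report/` contains `report.json`,
CSV tables of all regressions and group comparisons, and per-plot figure
data (`x, y, fit, band_low, band_high`).

The same battery runs on a real cohort table (CSV or XLSX with the canonical
column names) via `analyze-cohort`, and on real B-scans via `fit-speckle`
(pixel geometry from a JSON sidecar or `--axial-pixel-um`/
`--lateral-pixel-um` flags).

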