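# Methods

## Synthetic imaging model

The generator emulates a dark-room chlorophyll-fluorescence acquisition of
garlic-like leaves under five environmental conditions: a control (Cg), two
heat-stress levels (HL-1, HL-2) and two combined soil-moisture + heat levels
(MHL-1, MHL-2).

**Emission model.** A leaf's clean per-band signature is a sum of two
Gaussians on the wavelength axis: the chlorophyll red emission peak at
673 nm and the far-red shoulder at 717 nm,

    s(λ) = a₁·A₁·exp(−(λ−673)²/2σ₁²) + a₂·A₂·exp(−(λ−717)²/2σ₂²)

with base amplitudes A₁ = 1.0, A₂ = 0.55 (arbitrary fluorescence units) and
widths σ₁ = 12 nm, σ₂ = 28 nm — a minimal shape with the right extrema: the
argmax of the 25-band signature falls on the band nearest 673 nm and the
intensity decays toward 870 nm. Stress acts as multiplicative attenuation
(a₁, a₂) of the two amplitudes. The default study conditions are

| group | a₁ (peak) | a₂ (shoulder) |
|-------|-----------|---------------|
| Cg    | 1.00      | 1.00          |
| HL-1  | 0.85      | 0.80          |
| HL-2  | 0.72      | 0.65          |
| MHL-1 | 0.80      | 0.72          |
| MHL-2 | 0.55      | 0.45          |

chosen so that stressed leaves are dimmer overall (control dominates every
stressed signature pointwise) and the shoulder is attenuated slightly more
than the peak, so red/far-red band ratios also carry group signal. With
symmetric attenuation the ratio cancels amplitude stress exactly — a property
the tests exploit — which is why the defaults are asymmetric.

**Scene model.** Each acquisition is a 64×64×25 cube (configurable). The
leaf is a random union of 2–3 overlapping ellipses near the image center;
leaf pixels carry `illum · (g·s + o)` where g ~ N(1, 0.08²) and
o ~ N(0, 0.01²) are per-leaf multiplicative gain and additive offset
(leaf-to-leaf scatter), and `illum` is a radial illumination falloff (25%
from center to the farthest corner by default). All pixels gain dark current
(0.05) and i.i.d. Gaussian sensor noise (SD 0.01 per pixel-band). The white
reference is the same illumination field times a flat panel response of
1.2·(A₁+A₂), the dark frame is dark current plus noise. Band centers are
uniform over 603–870 nm (spacing 11.125 nm); real cameras have irregular
centers, which nearest-band matching absorbs.

What the generator does **not** model: shot noise (noise is signal-
independent), partial-volume mixing at leaf boundaries, specular/cuticle
reflections, leaf morphology, temporal stress dynamics, or radiometric
exposure effects. Passing tests therefore demonstrate the correctness and
statistical behavior of the analysis chain under a known ground truth, not
performance on real leaves.

## Calibration, masking, ROI

Flat-fielding is `(raw − dark)/(white − dark)` elementwise. Pixel-bands with
white == dark become NaN and are counted rather than raising (real panels
can clip). In the noiseless limit the operation recovers signature/panel on
leaf pixels exactly; note that with nonzero dark current the float64
subtraction (x + d) − d limits achievable relative accuracy to ~1e−11 at
bands where the signal is ≪ d — an arithmetic, not algorithmic, effect.

Masks threshold the band nearest 673 nm (maximal leaf/background contrast)
with Otsu's method by default; the threshold, band and method are recorded
on the mask. Masking operates on the calibrated cube. ROI spectra are drawn
uniformly without replacement from mask-true pixels, deterministically per
seed, with per-row provenance (scene, row, column); the default budget is
400 spectra per group, split evenly across the group's scenes.

## Spectral pretreatments

The three pretreatments are mutually exclusive alternatives (matching the
three model columns the comparison tables report):

* **Smoothing** — Savitzky–Golay, window 5, polyorder 2 by default
  (moving-average offered); edges handled by symmetric reflection so the
  band count is preserved. Linear, hence constant-preserving.
* **MSC** — per-row least-squares fit x ≈ a + b·ref, corrected to
  (x − a)/b. The reference is the calibration-split column mean, frozen and
  reused on prediction rows and map pixels so no information crosses the
  split. Rows with |b| < 0.05 are flagged and returned unchanged: such
  spectra (background pixels admitted by the mask, noise-dominated rows)
  carry essentially none of the reference shape, the affine model is
  unidentifiable, and dividing by b would amplify noise without bound.
* **SNV** — per-row standardization to mean 0, sample SD 1 (n−1 denominator
  throughout the package). Constant rows cannot be scaled and are excluded
  (or zero-filled when row alignment must be preserved, e.g. whole-image
  scoring).

## PLS-DA

Pairwise one-vs-one binary models (the reported accuracy tables are strictly
pairwise); classes coded 0/1, cutoff 0.5 on the continuous prediction.
Fitting is NIPALS PLS1 on column-centered X and centered y — deterministic,
no random initialization — with β = W(PᵀW)⁻¹q and intercept ȳ − x̄·β. Two
algebraic identities are enforced by tests: the scores-path and beta-path
predictions agree to 1e−10, and at k = rank(X) the fit equals ordinary least
squares to 1e−8 (scikit-learn's PLS is used as an additional independent
cross-check).

The number of latent variables k is chosen per pair by stratified 5-fold
cross-validation on the calibration split, minimizing misclassification with
ties broken toward the smallest k, capped at k_max = 10. The 75/25
calibration/prediction split is stratified by class (per-class calibration
count = round(0.75·n)). Pretreatment state (MSC reference) is fit on the
calibration rows only.

Score maps apply the frozen pretreatment and β to every mask pixel; raw
scores are returned (NaN off-mask) and clipped to [0, 1] only for display
and group statistics.

With broad emission Gaussians the class-difference spectrum can genuinely
peak on a band adjacent to a nominal center, so beta-coefficient wavelength
reports should be read at band-distance resolution; with well-separated
peaks (widths ≲ band spacing) the top-|β| bands localize on the bands
nearest the two centers.

## Statistics and model comparison

One-way fixed-effects ANOVA (F from SSB/SSW, p from the F distribution;
zero within-variance with unequal means reports F = +inf, p = 0). Tukey HSD
uses the studentized range with Tukey–Kramer standard errors for unequal n;
compact letters are assigned by insert-and-absorb with groups ranked by
descending mean. The parametric p agrees with a permutation null within
Monte-Carlo error for continuous data at moderate n; at 2–3 observations per
group with ties the permutation null is too discrete for such agreement —
tests use n = 20 per group for that check. Map pixels are treated as
independent observations, as is conventional in imaging phenotyping tables;
spatial autocorrelation within a leaf makes the resulting p-values
anti-conservative, a documented (not modeled) caveat.

Model comparison reports, per model family, the mean over all 10 group pairs
of R² = 1 − SS_res/SS_tot and RMSE of continuous predictions against the 0/1
codes on the prediction set. The "ratio model" is a univariate least-squares
regression of the class code on the ratio value, fit on calibration rows;
ratio features are winsorized to the calibration split's (0.5, 99.5)
percentile band first, mirroring the noise trimming applied to map
statistics, because a single stray background pixel otherwise yields an
unbounded ratio and dominates SS_res.

## Numerical and design choices

* Nearest-band substitution (never interpolation) maps named ratio
  wavelengths to camera bands; ties break toward the lower wavelength and
  every substitution is logged.
* Percentile trim for map statistics defaults to (0.5, 99.5), two-sided,
  values outside the band dropped before mean/SD/range.
* Ratio maps are invariant to global cube scaling — bit-exactly for
  power-of-two factors, to one rounding step otherwise.
* Cube container: single-file `.npz` (data, wavelengths, JSON metadata),
  lossless for float64; multi-page TIFF export offered for viewing.
* All dataset/pipeline randomness derives from one master seed via
  `numpy.random.SeedSequence`; identical (config, seed) reruns are
  bit-identical, including CSV artifacts.
* Problem sizes used by the test suite and the acceptance script (48–64 px
  scenes, 100–400 spectra per group, 10–20 seed replicates) were chosen as
  the smallest sizes at which the statistical properties under test are
  stable.

## Known limitations

No geometric registration, no specular/cuticle handling, no 5-class
simultaneous PLS2, no variable-selection wrappers (VIP/iPLS), no nonlinear
kernels, no spatial statistics. The linear PLS-DA assumption itself is a
limitation for strongly nonlinear stress responses.
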