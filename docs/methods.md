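# Methods

## Data model

One row per regenerant: integrated absorbance areas over the 710–690 and
1010–940 cm⁻¹ windows (`f710_690`, `f1010_940`) and their sum
(`f_combined`), the metAFLP quantitative characteristics — total
demethylation `dmv` with CG- and CHG-context components and sequence
variation `sv`, all percentages — plus the culture trial (M1–M9) and
culture duration (21/28/35 days). Two additivity invariants are enforced
at load time: `f_combined = f710_690 + f1010_940` (|Δ| ≤ 1e-4, the
resolution of the four-decimal inputs, compared inclusively) and
`dmv = cg_dmv + chg_dmv` (|Δ| ≤ 5e-3). The packaged 35-row study table
passes both on every row; its row-35 `dmv` value is stored as 2.0940,
repairing an obvious typographic space in the source table.

## Spectral preprocessing

Spectra are (wavenumber, absorbance) pairs on a uniform grid, 4000–400
cm⁻¹ at 4 cm⁻¹ for instrument-like data, stored high→low. All operations
are orientation-agnostic.

* **Baseline** — the proprietary instrument-software correction is
  replaced by a documented anchor-window scheme: each anchor window
  contributes a knot (window midpoint, mean absorbance), the baseline
  interpolates linearly between knots and extrapolates the end segments
  linearly. One anchor degenerates to offset subtraction; two give the
  classical two-point linear baseline. Water-vapour correction is out of
  scope (no raw spectra exist to correct); a provenance tag records the
  omission.
* **Area normalization** — the whole spectrum is divided by its
  trapezoidal integral over 1800–900 cm⁻¹, making that integral 1. The
  operation is idempotent and scale-invariant to 1e-12.
* **Band integration** — trapezoid on the native grid, window edges
  included by linear interpolation; additive over adjacent windows to
  1e-10. Band areas are computed on the normalized spectrum by default
  (normalize-then-integrate); both orders are available since the original
  ordering is not documented.
* **Fragmentation** — fixed-width tiling (default 10 cm⁻¹) from the
  high-wavenumber end; a trailing narrower remainder is kept and flagged
  `partial`. The full 4000–400 cm⁻¹ range yields 360 windows.
* **Deconvolution** — nonlinear least squares (`scipy.optimize
  .least_squares`) of a Gaussian sum over 1200–600 cm⁻¹ by default.
  Parameters are (center, height, fwhm) per band with nonnegativity
  enforced by fitting absolute values; budget 10 000 function
  evaluations, relative tolerance 1e-10; non-convergence is reported via
  a flag, never raised; the returned residual sum of squares never
  exceeds that of the initial guess.

## Mediation

Three OLS regressions (classical, homoskedastic standard errors, through
statsmodels): `m ~ x` gives `a`; `y ~ x + m` gives `c'` and `b`;
`y ~ x` gives `c`. `IE = a·b`, and `c = c' + a·b` holds to 1e-8 by OLS
algebra — asserted on every dataset the tests touch. Reported alongside:
partially standardized IE (`IE/SD(y)`), completely standardized IE
(`IE·SD(x)/SD(y)`, sample SDs with n−1), and `VAF = 100·IE/c`.

**Bootstrap.** Case resampling with a seeded `numpy` Generator; default
5000 draws, 95% percentile interval (bias-corrected percentile available;
which flavour the original analysis used is not documented, percentile is
the macro-convention default). Per-resample refits are closed-form — the
`a` path as cov/var, (`c'`, `b`) by 3×3 normal equations — vectorised over
all resamples; a unit test pins this against explicit statsmodels refits.
Resamples that collapse a design to singularity yield non-finite draws and
are dropped from the quantiles.

**Goodman test.** `Z = ab / √(b²s_a² + a²s_b² − s_a²s_b²)`, two-sided
normal p. When the subtracted term makes the denominator nonpositive the
Sobel denominator is used and the fallback is flagged. |Z_Goodman| ≥
|Z_Sobel| whenever Goodman's denominator is positive (property-tested).
The Goodman-I form is anticonservative when both paths are null — the
reason the window screen's false-positive behaviour is validated under
`a = 0` with a live `b` path, the realistic null for this design.

**Effect size.** `f² = r²/(1−r²)` for power planning; at the planning
value r² = 0.1, f² = 0.111.

## Moderated mediation

Default structure: the moderator (culture time, days, uncentered) enters
both stages — `M ~ X + W + X·W` and `Y ~ X + W + M + M·W` — with no `X·W`
term in the outcome model. This is the structure the published degrees of
freedom imply (outcome F on (4, 30), mediator interaction test on (1, 31)
at n = 35) and it reproduces every printed coefficient; the `X·W`-in-
outcome variant sits behind `ModMedSpec(moderate_cprime=True)` (outcome
df_resid 29 at n = 35). Raw products, no mean-centering, matching the
published coefficient scale.

* **Conditional indirect effect** `θ(w) = (a₁ + a₃w)(b₁ + b₂w)` — exact
  algebra on the fitted coefficients (recomputation reproduces the
  reported value to 1e-12); its SE and CI come from a seeded
  case-resampling bootstrap of the whole two-equation system, since the
  product of two estimated linear forms has no exact normal-theory SE.
* **Interaction F test** — nested-model `F = (ΔR²/df₁)/((1−R²_full)/df₂)`
  with ΔR² reported.
* **Johnson–Neyman** — for a moderated path `θ(w) = β₀ + β₁w` with
  `Var θ(w) = v₀₀ + 2w·v₀₁ + w²·v₁₁`, the significance boundaries solve
  `θ(w)² = t²_crit·Var θ(w)`, a quadratic solved in closed form
  (t critical from the path's model residual df). Roots outside the
  observed moderator range are dropped and reported as "none within
  range"; direction flags say on which side the path is significant. A
  0.01-step grid scan is the test oracle.
* **Aggregate decomposition** — with a moderated model no single
  indirect/direct split is canonical. The convention here: aggregate
  indirect = `a₁·b₁` (the first-order path product), direct = `c₁'`,
  `VAF = 100·indirect/(indirect + direct)`. On the study table this gives
  indirect ≈ 2805, total ≈ 2846, VAF ≈ 98.6%.

## Window screen

Each 10 cm⁻¹ window's integrated absorbance across samples is the
predictor of a simple mediation against the shared mediator and outcome.
Per-window bootstrap seeds are `master_seed XOR window_index` (masked to
31 bits), so results are independent of evaluation order and a
single-window scan is bit-identical to a direct mediation call.
Significance defaults to the bootstrap CI excluding zero; Goodman p-values
are reported raw and Benjamini–Hochberg adjusted (statsmodels
`multipletests`) so that multiplicity across ~360 windows is visible —
the uncorrected decision rule remains available as a flag. Zero-variance
windows are skipped with a warning.

## Synthetic data

**Spectra** are Gaussian-band sums at the twelve fingerprint centers
(1153, 1104, 1069, 1036, 991, 960, 896, 825, 719, 710, 701, 670 cm⁻¹) on
the instrument grid, plus optional linear baseline drift and white noise.
Default heights/widths mimic the region's shape: dominant polysaccharide
bands at 1069/1036 (height 1.0/0.9, fwhm ≈ 30 cm⁻¹), small shoulder bands
at 991/960, and a narrow low-frequency triplet at 719/710/701 (height
0.25–0.30, fwhm 8 cm⁻¹) whose 9–10 cm⁻¹ separations make it the hardest
identifiability case on the 4 cm⁻¹ grid; the chosen amplitudes keep all
twelve centers localizable within 2 cm⁻¹ at 1% (of maximum) noise when
fits start from the nominal centers, which is how band fitting is done in
practice. Selected peak heights can be tied to a latent per-sample factor
(`effect_map`) to plant a spectral signal.

**Mediation datasets** draw x uniformly over the observed
combined-absorbance range (0.02–0.06), time from {21, 28, 35} days, then
`m = 1.5 + (a + a₃w)x + N(0, sd_m)` and
`y = 10 + c'x + (b + b₂w)m + N(0, sd_y)` with defaults sd_m = 0.1,
sd_y = 0.5 — residual scales of the same order as the study table's
regression residuals. Output uses the regenerant table schema (mediator
emitted as the CHG-context column, CG set to zero) and always passes its
validation; m and y are clipped at zero to respect the percentage
domain, which the default intercepts make a measure-zero event. Exact
zero mediator noise is not a usable test case: it makes m exactly affine
in x and the outcome design singular.

What the generators deliberately do not emulate: correlated (pink)
instrument noise, ATR penetration-depth effects, non-Gaussian band
shapes, the discreteness of metAFLP percentages, and trial-level
clustering. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data features.

## Validation sizes and numerical choices

Deterministic reproductions run on the packaged 35-row table. Stochastic
checks use: 1000 replicates at n = 500 with 1000 bootstrap draws for CI
coverage (observed 94.6% at nominal 95%); 500 replicates at n = 200 for
the null-path type-I rate (observed ≈ 5.8%, asserted within 2–9%); 20
seeded replicates for deconvolution recovery and moderated-path parameter
recovery (median relative error ≤ 10% at n = 500); 100 seeded runs of a
30-window null screen for false-positive control. Sizes were chosen so
the whole suite runs in about a minute on one CPU while keeping Monte
Carlo error well inside the asserted bands.

## Known limitations

* The 710–690 cm⁻¹ band areas are ~1e-3 and carry only one–two
  significant figures in the study table; statistics of models using that
  band alone are sensitive to the input rounding at the several-percent
  level (its completely standardized IE is stable; its VAF is not).
* Classical OLS standard errors throughout (robust variants exist behind
  a flag but are not needed to reproduce the published analysis); n = 35
  leaves little power to check homoskedasticity.
* No multiple-mediator, serial-mediation, or causal sensitivity analysis;
  the windowed screen is univariate per window, not a multivariate
  chemometric model.
* JCAMP-DX reading is not implemented; spectra are exchanged as
  two-column CSV.
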