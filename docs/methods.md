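# Methods

## The assay model

The package implements the data analysis of a kinetic spectrophotometric
assay built on triiodide reporting chemistry. In aqueous solution, iodate
and iodide comproportionate under acid to the yellow triiodide chromophore,

    IO3- + 8 I- + 6 H+  ->  3 I3- + 3 H2O,

read near 350 nm. When the analyte is a hydrochloride salt it supplies the
protons, and with both iodine reagents in large excess the colour-formation
kinetics are pseudo-first-order in the analyte. The absorbance-time trace
of each cuvette is therefore modelled (and, in the generator, simulated) as

    A(t) = baseline + s_inf * C * (1 - exp(-k_obs * t)) + e,   e ~ N(0, sigma^2),

with `C` the analyte concentration in ug/ml (= mg/L), `s_inf` the long-time
(plateau) calibration sensitivity in AU per ug/ml, `k_obs` the observed
rate constant in 1/s, and homoscedastic Gaussian reading noise. Everything
downstream treats measured curves empirically; no mechanistic rate law for
the iodate-iodide system is integrated.

## The four calibration methods

Each method maps a set of standard curves to an ordinary least-squares
line, `y = m x + b`:

1. **Initial rate.** The response is the slope of the tangent at t -> 0,
   estimated by OLS over all points with `t <= window_end` (default 600 s,
   i.e. the first three points of a 300 s grid — the early-linear region of
   a rising exponential; exposed as a parameter). The calibration line is
   log-log: `log10 v = log10 k' + n log10 C`, so its slope is the reaction
   order `n` and `10^intercept` the pseudo-order rate constant `k'`. On
   noise-free generator output the recovered order is exactly 1, since the
   initial rate is `s_inf * k_obs * C`. Note that published treatments of
   this chemistry report `k'` as the *antilog of the intercept magnitude*
   (the intercept itself is negative for sub-unit rates); the package
   computes `10^intercept` and documents the magnitude convention rather
   than silently adopting it.
2. **Rate constant.** Each curve is reduced to
   `k' = -2.303 * slope(log10 A vs t)` — the classical graphical recipe
   with the printed 2.303 factor kept verbatim so the arithmetic of a lab
   notebook can be audited (using `ln 10 = 2.302585...` would change
   results by 1.8e-4 relative). Readings with `A <= 0` (typically t = 0)
   are excluded with a warning. `k'` is regressed on concentration over a
   configurable sub-range (default 1-8 ug/ml). For a truly
   pseudo-first-order system k' carries no concentration information, so
   the model attaches a suitability warning whenever r^2 < 0.99; the
   method is implemented because practitioners scan all four, not because
   it is expected to calibrate well. The log fit is applied to the rising
   curve exactly as practised in this assay literature; the conventional
   first-order linearisation would use `log(A_inf - A)` and is deliberately
   not substituted.
3. **Fixed absorbance.** The response is `1/t`, with `t` the first time the
   piecewise-linear curve reaches a preset absorbance (default 1.2 AU).
   Standards that never reach the target are excluded with a warning.
4. **Fixed time.** The response is the absorbance at a preselected time
   (linear interpolation between grid points, no extrapolation, no
   smoothing). `select_fixed_time` refits the calibration at each candidate
   time and keeps the highest r^2, breaking ties toward the earliest time —
   a shorter assay at equal linearity.

Inverse prediction applies the model's y-transform to a raw response,
solves the line, and undoes the x-transform; estimates outside the fitted
linear range are flagged, not rejected. Predict-then-invert is an identity
to 1e-9 relative for every method.

An opt-in relative-response screen drops standards whose response per unit
concentration falls outside 98-102% of the mean relative response (mean
computed once, boundaries inclusive). It is off by default because it is a
replicate-level acceptance rule, not part of the least-squares machinery.

## Validation battery

* **Recovery/RSD** per level: recovery % = 100 * found/taken,
  RSD % = 100 * SD/mean with the sample (n-1) SD. Values are stored at
  full precision; the report renderer rounds to two decimals.
* **LOD/LOQ** = 3.3 sigma/m and 10 sigma/m (ICH Q2 convention) with sigma
  the residual SD of the calibration line, `sqrt(SSE/(n-2))`; undefined
  (and refused) for two-point fits. The 10/3.3 ratio is constructive.
* **Molar absorptivity** epsilon = m * MW * 1000 / l converts a mass-
  concentration slope to L mol^-1 cm^-1. The molar mass of clindamycin
  hydrochloride (C18H33ClN2O5S.HCl, 461.44 g/mol) ships as an overridable
  constant.
* **Method comparison**: pooled-variance two-sample t (df = n_a + n_b - 2)
  and variance-ratio F with the larger variance in the numerator (F >= 1,
  dfs ordered accordingly); significance flags compare against the
  two-tailed t and upper-tail F quantiles at the requested confidence.
  Published tables in this literature sometimes quote the t critical value
  for n - 1 = 4 df alongside an F critical value for (5, 4) df; the
  package reports its df choices explicitly instead of forcing either
  convention.
* **Formulation assay**: each unknown curve is one work-up replicate; its
  response is inverted to a solution concentration and scaled to mg per
  dosage unit through an explicit dilution record (default: 50 mg
  label-equivalent dissolved in 50 ml, diluted 100-fold to ~10 ug/ml).

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical design the analysis assumes:
standards at {1, 2, 4, 8, 12, 16, 20} ug/ml, readings every 300 s from 0
to 2400 s, five replicates, single wavelength, 25 C. Defaults
`s_inf = 0.119` AU per ug/ml and `k_obs = 4.5e-3` 1/s were chosen so the
fixed-time sensitivity profile `s_inf (1 - e^{-k_obs t})` matches the
slope progression of published fixed-time calibrations of this chemistry
(0.0883 AU.ml/ug at 300 s rising to 0.119 at 2400 s; the 300 s/2400 s
ratio agrees to ~0.2%). Noise is additive, Gaussian and homoscedastic at
0.001 AU — the level implied by published found-concentration SDs of
~0.01 ug/ml at the bottom of the linear range, and the largest
homoscedastic sigma for which the global precision claim (every RSD below
2% at five replicates) holds down to 1 ug/ml, where the relative error is
worst. Stoichiometry enters through `triiodide_yield`, a limiting-reagent
calculation on the balanced equation used for sanity checks and for
reasoning about reagent excess.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: heteroscedastic noise (real found-SDs
grow toward the top of the range), instrument drift and blank offsets,
excipient effects beyond a single multiplicative bias factor, temperature
sensitivity, and any departure from single-exponential kinetics (induction
periods, secondary reactions). Parameter-recovery results on synthetic
data are a correctness check of the estimators, not evidence about a
particular instrument.

Randomness: one root seed; each curve draws from a substream keyed by
(seed, concentration index, replicate index), so removing levels or
replicates from the design never shifts the remaining draws.

## Numerical choices

* OLS via `scipy.stats.linregress`; r^2 is clamped to [0, 1] and defined
  as 1 for a zero-residual fit even when the responses are constant.
* Interpolation and crossing-time searches are linear and unsmoothed; the
  crossing search returns the first segment bracketing the target, and a
  curve starting at or above the target returns its first time point.
* Times are seconds everywhere internally; minute-labelled CSV input is
  converted on read.
* The relative-response boundaries are inclusive with a 1e-12 relative
  guard so exact-boundary points survive float rounding.
* Wavelength is metadata only (default 350 nm) and never enters any
  computation.
* Error handling: every domain error carries a stable string code
  (e.g. `insufficient-standards`, `target-not-reached`, `domain-error`);
  the CLI maps data errors to exit code 2 and computational errors to 3.

## Problem sizes

The default design (7 levels x 5 replicates x 9 time points) is the study
condition itself, so tests and the acceptance script run it directly; the
law-of-large-numbers check uses 400 replicates of a single level. All
suites complete in a few seconds on one CPU.

## Known limitations

* The rate-constant method is implemented literally on log10 of a rising
  absorbance, which is not linear in time; it exists to reproduce the
  screening workflow (and its rejection), not to estimate k well.
* LOD/LOQ use the residual-SD convention only; blank-based and
  signal-to-noise definitions are out of scope.
* No weighted or robust regression, no multi-segment linearity, no
  Bland-Altman agreement analysis, no multi-wavelength spectra.
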