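# Methods

## System and scope

The package models two linked experiments on drug-loaded polymer filaments
produced by supercritical-CO₂ solvent impregnation (the reference system is
ketoprofen in 1.75 mm PLA filament):

1. a full 3² factorial of impregnation pressure (100/250/400 bar) and
   temperature (35/55/75 °C) with three measured responses — permanent
   swelling %, total drug loading % and superficial drug % — analyzed with a
   quadratic response surface, ANOVA, standardized Pareto effects and
   desirability optimization; and
2. in-vitro cumulative release curves Q(t) (fraction of total load, time in
   days) fit to five classical monophasic models and to a piecewise
   "multiphasic" power law with phase breakpoints.

Out of scope by design: mechanistic CO₂-sorption or polymer-degradation
models, pH/temperature dependence of release, models beyond the listed
ones, and any imaging or spectrophotometric laboratory procedure.

## Release models and conventions

Time is in days everywhere; Q is a dimensionless fraction at API
boundaries (percent only in rendered reports). Rate-constant units follow
each model: k₀, k₁ in day⁻¹, k_H in day^−0.5, k_KP in day^−n, k_d in
day^−m and k_r in day^−2m.

The printed first-order form Q = Q₀·e^{k₁t} grows without bound and cannot
start from zero release, so the package's default `first_order` is the
conventional saturating release form Q = 1 − exp(−k₁t); the literal
exponential is retained as `first_order_literal` for fidelity. Reported k₁
values of 0.055–0.102 day⁻¹ are consistent with the saturating form over
the 20–63 day observation windows.

Mechanism classification (cylindrical geometry only) uses the Ritger–Peppas
thresholds with boundaries inclusive on the anomalous side: n < 0.45
Fickian diffusion, 0.45 ≤ n ≤ 0.89 anomalous transport, 0.89 < n ≤ 1
case-II transport, n > 1 super case II. The super-case-II refinement is
standard and is needed because fitted phase-III exponents above 1 occur in
this system. Negative rate constants are accepted in evaluation (a negative
Peppas–Sahlin k_r is physically reported for one sample) but flagged in
pipeline reports.

## Monophasic fitting

The objective is ordinary least squares on untransformed Q (models are
compared by R² on the cumulative curve, so fitting a transformed scale
would bias the comparison). R² = 1 − SSE/SST with SST about the mean of
the observed fractions; it can be negative for mismatched models and is
reported as-is. Linear-in-parameters models (zero-order, Higuchi,
Peppas–Sahlin with fixed m) are solved in closed form; the rest are
initialized from a log–log (or semi-log) regression on the positive
observations and refined with `scipy.optimize.least_squares`, with an
8-start multiplicative perturbation multistart drawn from a fixed seeded
stream so fits are bit-for-bit reproducible. Peppas–Sahlin fixes m = 0.45
(the strictly-Fickian cylinder value) by default because no per-sample m is
reported; it can be freed, in which case SSE can only improve. No bounds
are imposed on exponents by default (fitted exponents up to ≈1.56 are
legitimate here); user bounds are supported. Model ranking sorts by
descending R², then fewer free parameters, then enumeration order, and a
model that errors is reported as failed rather than dropped.

## Multiphasic model

Segments are fit **independently on absolute time** with no continuity
constraint — this matches the piecewise definition of the model and the
reported per-phase R² semantics. A continuity-constrained or re-zeroed-time
variant was considered and rejected: the reported per-phase (k, n, Qᵢ)
triples are not mutually consistent under either reading (e.g.
0.359·5^0.2348 ≈ 0.52 against a printed Q₁ = 0.55, and the printed
phase-III parameters of the 400 bar sample evaluate to ≈1.16 at day 14
against a printed 0.97), so those values are treated as qualitative
anchors, not reproduction targets. For the same reason the per-phase
`q_end` is taken from the observed series at the last observation of the
segment, not from the fitted curve.

Phase labels: a 2-segment fit is {I_II, III}; a 3-segment fit {I_II, III,
IV}. Phases I and II are always modeled jointly (both are
diffusion-governed and not separable by a power law).

Breakpoint search is exhaustive over the observed time points, with a
minimum of 3 observations per segment (keeping the search exact and
reproducible at the study's profile sizes of 14–40 points); each admissible
partition is scored by total piecewise SSE and ties resolve to the earliest
breakpoints. How the original phase boundaries were chosen is not stated,
so automatic detection is this package's own concretization; user-supplied
breakpoints remain available for fidelity.

## Factorial analysis

Factors are coded affinely to {−1, 0, +1} and the quadratic predictors are
centered at their design mean (x² − 2/3), which makes the five columns
{x_A, x_B, x_A²−2/3, x_A·x_B, x_B²−2/3} mutually orthogonal on the
balanced design: each term then has a single-df sum of squares that is both
its sequential and partial SS, and the residual after the five-term model
(df = n − 6, i.e. 3 on nine runs) is the ANOVA error term. This model is
pinned by the reported tables themselves (error df = 3 with five single-df
terms). The error is the lack-of-fit residual — there is no replicate
pure-error split — and p-values come from the upper tail of the F
distribution with no multiple-testing correction, matching the original
analysis. `finalize_anova` applies exactly the same MS/F/p/R² arithmetic
to an externally supplied SS skeleton, which is how the four reported
tables are completed and cross-checked without raw data.

Standardized (Pareto) effects are signed t-ratios coefficient/SE with
SE = √(MS_error/Σx²); for single-df terms |t| = √F identically, and the
95% reference line is the two-sided t critical value at the error df.

Desirability optimization: each response surface is rescaled linearly
between its worst and best predicted value over the search domain
(larger-is-better for loading, smaller-is-better for swelling and
superficial load), combined as a weighted geometric mean
D = (Π dᵢ^{wᵢ})^{1/Σwᵢ}, and maximized on a dense deterministic grid
(1 bar × 0.5 °C). The original optimizer is unstated; this concretization
is documented and swappable, and the result is asserted only as a region
(high temperature, pressure below the mid level), not a point.

## Synthetic data

`generate_release_profile` evaluates the piecewise power law at a sampling
schedule denser early (0.5, 1, 2, 3, 4, 5 days, then every 2 days) to
resolve the burst, and adds Gaussian noise with σ = 0.01 by default (~1% of
full release, consistent with the smoothness of the published curves; the
measurement error is not printed, so this is the package's choice). Noise
is additive on the cumulative fraction by default; an increment-noise mode
guarantees monotone noisy curves. Fractions are clipped below at 0 and, by
default, above at 1 (`clamp_to_unit=False` disables the upper clip for
recovery experiments whose generating parameters exceed 1 inside the
window, in which case the profile is marked non-fractional).

`generate_factorial_dataset` draws the 9·replicates responses from the
quadratic model plus N(0, σ²). The fixture bundle (`paper_like_fixtures`)
uses the reported multiphasic phase parameters of the four analyzed
conditions as release-generating truth, and factorial generators whose
coefficients are the quadratic projection of 3×3 anchor cell-mean tables
interpolating the reported response values and trends; the fixture noise
SDs (0.39/0.38/0.15 for loading/swelling/superficial) are the replicate
standard deviations reported at the optimum condition, rather than the
ANOVA error MS, which also contains lack of fit.

What passing tests on these data do and do not show: they demonstrate that
the estimators recover known truth under the stated noise model and sample
sizes, that the ANOVA's type-I error is calibrated under normality, and
that the analysis reproduces the study's qualitative conclusions when the
data are generated at the reported parameter scales. They cannot validate
the physical models against real release curves (the raw curves are not
published), nor cover non-Gaussian or autocorrelated measurement error.

## Numerical choices and problem sizes

Nonlinear fits use `least_squares` with tolerances 1e-12 and a fixed
multistart stream; noiseless generated data are recovered to ≤1e-6
relative error. Degenerate inputs raise typed errors: constant responses
(SST = 0), perfect quadratic fits (error SS = 0, F undefined), partitions
with under-populated segments, rank-deficient or incomplete designs.
Monte-Carlo checks use 100 replicates for recovery experiments (40-point
profiles, σ = 0.01, breakpoint on the sampling grid) and 1000 null
datasets for the type-I calibration — enough for binomial standard errors
of ~0.7 percentage points around the nominal 5% rate; these sizes keep the
full suite and the acceptance script in the tens of seconds on one CPU.

## Known limitations

- Segments are fit independently, so the fitted multiphasic curve can be
  discontinuous at breakpoints; that is a property of the model as defined,
  not an artifact.
- Exhaustive breakpoint search is O(n^{phases−1}) in the number of
  observations and is intended for profile sizes typical of dissolution
  assays (tens of points), not for dense sensor streams.
- The desirability optimum depends on the rescaling domain; it is stable
  for the study-like fixtures but should be re-examined when surfaces are
  extrapolated beyond the design region.
- Only cylindrical-geometry exponent thresholds are implemented.
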