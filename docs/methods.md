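# Methods

## Model

Fenofibric acid kinetics after oral sustained-release fenofibrate are
described by a five-state system: drug amount in stomach (X1, mg) and
duodenum (X2, mg), fenofibric acid in the central compartment (X3, mg),
and meal calories in stomach (X4) and duodenum (X5).  All transfers are
first order.  Fenofibrate itself is not observed systemically: esterase
conversion is fast and complete, so metabolism and absorption are lumped
into a single rate constant `k_ma` from duodenum to the central
compartment.  The measured concentration is `X3 / (Vc/F)` in mg/L
(numerically equal to µg/mL).

Food enters through three mechanisms:

* **Gastric-emptying window.**  Drug gastric emptying is
  `TVkg · (1 + E_food)^w(t)` where the indicator `w(t)` is 1 from each
  meal until `MTIME2` (default 6.94 h) after it, and 0 otherwise
  (half-open window `[meal + MTIME1, meal + MTIME2)`; `MTIME1` fixed at
  0).  Under fasting the indicator is identically zero.  With multiple
  meals the window restarts at each meal.
* **Bile effect.**  The absorption rate is `k_ma · (1 + E_bile · X5)`,
  linear in the duodenal calorie amount.  A saturable alternative is out
  of scope: the shipped model is the linear one.
* **Food-type volume effect.**  `Vc/F` is multiplied by `1 + E_Vc1`
  (standard meal) or `1 + E_Vc2` (high-fat meal).  Because distribution
  itself is not food-dependent, the decrease in apparent volume is read
  as an increase in bioavailable fraction, fold = `1 / (1 + E_Vc)`.

**Calorie units.**  X4/X5 carry calories in units of 100 kcal
(`ModelParameters.calorie_unit_kcal`, configurable).  This scaling is the
only one under which `E_bile = 0.0239` reproduces the published fed-state
absorption rates (0.198·(1+0.0239·6.863) ≈ 0.23 h⁻¹ for 686.3 kcal,
0.24 h⁻¹ for 908 kcal); the source does not state the unit explicitly.

**High-fat calorie load.**  The source reports the high-fat meal as
1280 kcal in the meal-composition table but derives fed-state parameters
at 908 kcal.  We use 908 kcal for derived-parameter reporting (the only
value consistent with the printed +21.8%) and 1280 kcal as the high-fat
period's calorie load in the trial generator and simulation scenarios;
both are plain arguments, not constants.

**Stomach/duodenum volumes** (0.049/1/0.045 L) appear in no model
equation — every food effect acts on amounts — and are stored as
metadata only.

**Meal/dose timing.**  The capsule was taken 10 min after the meal; both
are placed at t = 0 by default.  The 0.167 h offset is negligible against
a 16.8 h gastric-emptying half-life of the drug (kg = 0.0412 h⁻¹).

## Statistical model

Log-normal inter-individual variability (IIV, `eta`) applies to `kg`
(shared with the calorie emptying rate `kg'`), `k_el` and `Vc/F`;
inter-occasion variability (IOV, `kappa`) applies to `k_el` and `Vc/F`
per crossover period.  Residual error is proportional,
`y = f·(1 + eps)`, `eps ~ N(0, sigma²)`.

Printed variabilities are %CV; defaults convert them with the direct
convention `omega = CV/100` (31.7, 86.3, 93% IIV; 44.9, 50.9% IOV).  The two IOV magnitudes are
reported inconsistently between prose and parameter listing in the
original report; the listing's assignment — 44.9% on `k_el`, 50.9% on
`Vc/F` — is adopted.  The exact
log-normal relation `omega = sqrt(ln(1+CV²))` is available via
`omega_from_cv(..., "lognormal")`.

### Estimation

FOCE with interaction, realised as per-subject penalized-mode
(empirical Bayes) estimation plus a linearised marginal likelihood:

1. Inner problem: Newton iterations with a Fisher-scoring Hessian and
   backtracking line search minimise
   `-2 log p(y|b) - 2 log p(b)` over `b = (eta, kappa_1..P)`;
   gradient tolerance 1e-6.  The subject-level surface can carry
   spurious modes in which an absurd deviate pair mimics the data
   (an absorption/elimination exchange); when the mode has any deviate
   beyond 5 prior SDs or the iteration stalls, a deterministic restart
   battery (±1 on each eta axis) is run and the best mode kept.
2. Subject objective: `r'C⁻¹r + log|C| + n·log 2π` with
   `C = G S G' + V`, `G = df/db` at the mode, `r = y - f + G·b̂`, and
   `V = diag(sigma²·f²)` evaluated at the conditional predictions
   (the "interaction").  For a linear model with additive error this is
   the exact marginal -2 log-likelihood (tested against the closed
   form).  The `2π` constants are included, so absolute OFV values are
   comparable only within this package; OFV differences are the
   meaningful quantity.
3. Outer problem: L-BFGS-B over transformed parameters — log for rates,
   volumes, `MTIME2`, sigma and all omega/pi; `log(1+x)` for `E_food`
   and `E_bile` (lower bound -1); a generalised logit onto (-1, 10) for
   `E_Vc1/E_Vc2`.  Finite-difference step 1e-4, warm-started inner
   modes across evaluations.  Standard errors (optional) from a
   central-difference Hessian of the OFV (step 1e-2 on the transformed
   scale), covariance `2·H⁻¹`, delta method back to the natural scale;
   RSE% = 100·SE/|estimate|.  No off-diagonal elements in Omega.

The Jacobian `G` is assembled from one finite difference for `eta_kg`
and one for `eta_kel` (the only ODE-coupled directions; step 1e-4), with
the occasion-level kappa columns equal to the corresponding eta column
restricted to that occasion and the volume columns exactly `-f`.

The default free set mirrors the published fit: all structural and food
parameters plus variabilities, with `kg'`, `k_out`, `MTIME1`, `MTIME2`
and the physiological volumes fixed.  `MTIME2` can be freed; the
integration grid is recompiled per candidate value so the objective
stays piecewise smooth.

### Numerical integration

Two solvers share the model definition and are cross-checked to ~1e-6
relative:

* a reference path (`solve_profile`): LSODA with rtol 1e-8 / atol 1e-10,
  hard restarts at every dose, meal and window edge, plus two auxiliary
  states accumulating eliminated drug and calories so mass balance is
  verifiable exactly;
* a fast path (`CompiledSchedule`): classical RK4 on a precomputed node
  grid whose intervals never straddle a discontinuity (maximum step
  0.05 h), JIT-compiled with numba.  The likelihood, VPC and cohort
  simulation use this path; one 72 h solve costs ~30 µs.

The fasted drug cascade and the calorie subsystem also have closed
forms, used as independent oracles in tests; the calorie solution
switches to its equal-rate limit when `|k_out - kg'| < 1e-8` (the
published values, 0.00971 vs 0.00972 h⁻¹, nearly coincide).

## Synthetic data

`generate_trial` emulates the source study design: 24 subjects, three-way
crossover (fasted / 686.3 kcal standard / 1280 kcal high-fat), one
250 mg dose per period, sampling at 1, 2, 3, 4, 5, 6, 8, 10, 12, 24, 48,
72 h, IIV per subject, IOV per period, proportional error per sample.
Washout is 168 h and periods are simulated independently (no carryover —
appropriate for single-dose crossover with a 2.6 h elimination
half-life).  Negative simulated concentrations are re-drawn rather than
truncated so the proportional error keeps its CV interpretation; the
redraw count is recorded (≈1–2% of samples at sigma = 0.608).  Pre-dose
samples are emitted with DV = 0 and flagged missing.  Two frozen
fixtures ship with the package (6 and 24 subjects, seeds 101 and 202)
and a test regenerates them from their seeds.

What the generator does not emulate: demographic covariates (they play
no role in the final model), BLQ censoring, sampling-time deviations,
dropouts, or carryover.  Passing recovery tests therefore demonstrates
estimator correctness under the model's own assumptions, not robustness
to real-data pathologies.

## Simulation scenarios

`simulate_cohort` reproduces the published multiple-dose experiment:
1000 individuals per group, once-daily 250 mg for 7 days with the
group's meal before each dose (group calories 0 / 400 / 1280 kcal),
residual-error-free individual predictions on a 0.25 h grid, Cmax as the
grid maximum and AUC by trapezoid over the 168–192 h window, IOV drawn
once per individual.  Cmax's grid-location error is bounded by the local
curvature over a 0.25 h step and is far below the Monte-Carlo SE at
n = 1000.

**A reproducibility caveat.**  The published exposure table pairs
Cmax = 3.17 µg/mL with AUC(168→192) = 319.14 µg·h/mL for the fasted
group.  These are mutually inconsistent for a 24 h window, since
AUC over a window cannot exceed its width times Cmax (24 × 3.17 =
76.1 ≪ 319.14); in all three groups the printed AUC ≈ 100 × Cmax.  We
explored 7 vs 8 daily doses, window vs cumulative AUC, both %CV→omega
conventions, daily vs first-day-only meals, and population mean vs
typical subject: no combination reproduces the printed pair, and the
printed between-group ratios (≈1.37/1.52) disagree with the fold
changes the model itself implies at steady state (1.65/1.86).  The
package therefore reports what the stated procedure actually produces
(mean Cmax ≈ 7.3 µg/mL, mean AUC ≈ 130 µg·h/mL under the conventions
above) and the corresponding acceptance checks are expected to fail
against the printed numbers.

## Diagnostics

* `residual_table`: PRED (random effects at zero), IPRED (at the EBEs)
  and CWRES (marginal residuals decorrelated by the Cholesky inverse of
  the linearised covariance).  On data simulated from the model, CWRES
  is approximately standard normal (tested: mean within ±0.1, variance
  within [0.8, 1.2] at ≥500 observations).
* `vpc`: replicate datasets simulated at the design of the input (same
  subjects, times, meals, doses; residual error included), stratified by
  food type, binned at the nominal sampling times (the design is a fixed
  schedule; explicit bin edges are accepted and empty bins raise).
  Default 1000 replicates; the 5th/50th/95th observed percentiles are
  compared with their simulated 95% confidence bands.
* `bootstrap`: the internal-validation procedure the model was published
  with — each replicate draws 90% of subjects *without* replacement and
  refits; medians and 95% percentile intervals are reported.  Classical
  resampling with replacement is available via `method="resample"`
  (with re-numbered subject copies).  Non-converged replicates are
  recorded; >50% failures raise.

## Problem sizes used in the shipped checks

Parameter recovery runs the full 24-subject three-way crossover with 14
free parameters (seed 0, ~1–2 min).  The VPC self-calibration check uses
200 replicates; the bootstrap mechanics checks use 3–50 replicates on
6–12 subject datasets; the exposure simulation uses the full n = 1000
per group.

## Known limitations

* `k_ma` and `k_el` are nearly exchangeable (flip-flop) in fasted data;
  only the food effects and the IIV structure separate them.  At the
  published variability magnitudes (86–93% IIV, 60.8% residual CV) the
  likelihood on a 24-subject realization can genuinely prefer a
  partially exchanged mode, so recovery of the typical values to within
  a few tens of percent is realization-dependent — a property of the
  design and model, not of the optimizer (verified against an
  importance-sampled exact marginal likelihood).
* FOCE-I is an approximation; variability parameters (especially
  `omega_kel`, `sigma`) carry the usual downward finite-sample bias.
* The VPC is not prediction-corrected; with fixed designs and
  nominal-time binning this is adequate, but adaptive designs would
  need pcVPC.
* Absolute OFV values include the Gaussian constants and are not
  comparable with other software's OFV scales.
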