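# Methods

## Model

`gvhdtte` models the time from allogeneic hematopoietic stem-cell
transplantation (HSCT) to the first diagnosis of grades II–IV acute
graft-versus-host disease (aGvHD), right-censored at day 100, at dropout,
or at a switch of immunosuppressive prophylaxis. The survival function is
parametric, `S(t) = exp(-H(t))` with `H(t) = ∫₀ᵗ h(s) ds`; all structure
lives in the individual hazard `h(t)`.

Candidate baseline hazards are the proportional (`h = λ`), Weibull
(`h = λα(λt)^{α-1}`), Gompertz (`h = λe^{αt}`) and Bateman
(`h = f·ka/(ka−ke)·(e^{−ke t} − e^{−ka t})`) families. The final model
replaces the Bateman absorption phase with a chain of `n` transit
compartments (an Erlang-distributed onset delay):

```
T₁(0) = 1,  dTⱼ/dt = k_tr (Tⱼ₋₁ − Tⱼ),  j = 1..n
dA/dt = k_tr·Tₙ − kel_i(t)·A,           A(0) = 0
h_i(t) = f · m_static,i · m_wbc,i(t) · A(t)
```

The inflow `k_tr·Tₙ(t)` equals the Erlang(n, k_tr) density, so for a
constant elimination rate `A` is the Erlang⊗exponential convolution
`A(t) = e^{−kel·t} (k_tr/(k_tr−kel))ⁿ P(n, (k_tr−kel)t)` (with `P` the
regularized lower incomplete gamma function) — used throughout the test
suite as an independent oracle for the ODE solver.

Covariate effects:

* **static multipliers** on the hazard: matched related donor
  (λ_MRD = 0.773), female donor with male recipient (λ_sex = 1.45), and
  fludarabine + total-body-irradiation conditioning (λ_Flu = 0.768); a
  reference patient (all flags false) has multiplier 1;
* **WBC count** (time-varying): `m_wbc(t) = (WBC(t)/median(t))^γ_WBC` with
  γ_WBC = 0.125, centred on the *daily population median* WBC count, so a
  count equal to the day's median leaves the hazard unchanged. The
  power-of-ratio form is pinned down by the pair of published worked
  examples (−22.3% at 0.3 vs 2.3 cells/nL, −6.6% at 2.7 vs 4.7): a single
  exponent reproduces both, whereas a difference-exponential form would
  need exponents differing by a factor of ~4 (see
  `test_wbc_effect_is_ratio_power_not_difference_exponential`);
* **CsA exposure and patient age** act on the elimination rate:
  `kel_i(t) = k_el · (1 + 0.00309·(CsA(t) − 250)) · (age/54)^{−0.97·rel}`
  with `rel = 1` for related donors only. Higher CsA troughs and (for
  related donors) younger age speed up the post-peak hazard decline.

Parameter defaults (`FinalModelParameters`) are the reference estimates:
k_tr = 0.619/d, k_el = 0.0616/d, f = 0.0339/d. The transit-chain length is
a structural reconstruction: `n = 7` compartments with k_tr = 0.619 give
the estimated mean transit time 7/0.619 ≈ 11.3 d, and this structure
reproduces the published CsA (≈ +7/27/66% at days 10/20/30 for 100 vs
250 ng/mL) and age (≈ −5/16/30%) hazard-ratio examples to within rounding.
`n` is exposed as a configuration field. The half-life of the hazard
decline is ln 2 / k_el ≈ 11.3 d. The reference-patient hazard peaks at
day ≈ 16.3 on a 0.1-day grid; the published "day 17 (population median)"
plausibly refers to the median over individual patients' peak days, which
is not computable for the reference profile alone.

## Numerics

* Time runs from 0 (transplantation) to 100 days, as floats.
* Longitudinal covariates are carried forward between measurements (LOCF);
  the first value is carried backward to day 0. This matches how trough
  concentrations are interpreted clinically.
* The effect state is integrated by fixed-step RK4 (default 0.1 d) with
  the forcing and elimination rate evaluated at the exact half-step
  points; agreement with the closed-form convolution is ~1e−9 relative,
  and halving the step changes H(100) by < 1e−6 relative. The inner
  recursion is JIT-compiled (numba) with an identical pure-numpy fallback.
* H(t) uses trapezoidal quadrature on the same grid; the likelihood
  interpolates h and H linearly at event times.
* WBC counts are floored at 0.01 cells/nL before the power transform
  (zero counts occur after conditioning); the CsA linear factor on k_el is
  floored at 0.01 so extreme low exposures cannot make the rate negative.
  Both floors warn in scalar use and are silent inside the vectorized
  fitting path.
* The Bateman family handles `ka = ke` by its analytic limit
  `f·ka·t·e^{−ka t}`, not by epsilon perturbation.

## Estimation

The log-likelihood of right-censored data is
`Σᵢ [dᵢ log h(tᵢ) − H(tᵢ)]`; the objective function value (OFV) is
−2 log L. No random effects are estimated — the reference analysis reports
none — so exact maximum likelihood applies. Optimization runs Nelder–Mead
from moment-based initial values (the median onset time seeds the transit
rate) followed by a BFGS polish; positive parameters (rates, scale,
multiplicative λ's, the Weibull shape) are log-transformed, exponents and
the CsA slope — and the Gompertz shape, whose natural null value is 0 —
are untransformed. Standard errors come from the inverse observed
information (central finite-difference Hessian, relative step 1e−4) on the
natural scale; a singular information matrix yields "standard errors
unavailable" rather than a failure.

Nested models are compared by likelihood-ratio tests (χ² on the OFV
difference). Forward covariate selection adds, at each step, the candidate
with the smallest LRT p-value below 5%, skipping candidates whose design
column is degenerate in the data.

Five-fold cross validation partitions patients at random, refits on each
4/5 and compares held-out observed event times with model-simulated ones
by a two-sample log-rank test. The per-fold p-value is the **median over
20 simulated replicates** of the held-out fold: a single-replicate p-value
is uniform under the null, so even a perfectly specified model would fail
an "all folds p > 0.10" check ~40% of the time, while the median
concentrates near 0.5 under the null and remains small under
misspecification. A caveat found while validating this harness: the
log-rank statistic has essentially no power against a *constant-hazard*
misfit of delayed-onset data, because the maximum-likelihood constant
hazard matches the 100-day incidence and the hazard curves cross; a
Kolmogorov–Smirnov comparison of event-time distributions detects that
misfit decisively and is used as the negative control in the test suite.

## Simulation

Event times are drawn by inverse-transform sampling on the individual
cumulative hazard (linear interpolation between grid points; censoring at
day 100 when `H(100) < −log u`). Replicated cohort simulation yields
visual-predictive-check bands (pointwise 2.5/50/97.5 percentiles of the
replicate incidence curves; the observed curve is 1 − Kaplan–Meier).

Adjusted risk ratios toggle the exposure counterfactually on the *same*
simulated individuals, keeping all other covariates as observed and
sharing the uniform draws between arms within a replicate; the RR is the
replicate-median ratio of 100-day incidences with a 2.5–97.5 percentile
interval. Replicates with zero reference incidence are dropped and
counted.

CsA-adaptation analyses ask which constant CsA level gives a risk profile
the same 100-day incidence as a reference profile. Incidence for a
constant-CsA profile is computed analytically as `1 − S(100)` (the
large-replicate limit of the simulated median incidence), with the WBC
course pinned to the population median since future counts cannot be
conditioned on; the level is found by root bracketing over 50–600 ng/mL
(tolerance 0.1 percentage points of incidence). Unreachable targets are
reported at the range boundary with a flag.

## Risk stratification

For a landmark day (7, 14 or 21), each patient's model-based H(cutoff) is
compared with the cohort's interpolated sample median: strictly above →
high risk, at or below → low risk (deterministic tie rule). This is a
landmark analysis: patients whose event or censoring precedes the cutoff
are excluded (reported, with a warning) because their post-landmark
outcome is not observable. The median is computed on the dataset being
stratified; applying a training-set median to a test set is possible by
stratifying the combined grids.

## Synthetic cohorts

The clinical source data are access-restricted, so the generator
reproduces the statistical structure the analysis assumes; its defaults
are the study conditions and are not adjusted per test:

* n = 1479 adults, optional 3:1 train/test split, day-100 administrative
  censoring plus exponential dropout (~10% by day 100, echoing observed
  death/relapse attrition without modelling them as competing risks);
* static covariates: median age 54 (truncated normal, range 17–76, SD 13),
  22% female-donor→male-recipient, 40% related donors, 30% matched related
  donors, 23% FluTBI;
* WBC: a log-space piecewise-linear template through (0, 5.0), (8, 0.055),
  (20, 2.3), (30, 4.7), (41, 6.0), (70, 3.9) cells/nL, flat thereafter
  (the day-0 value 5.0 is a plausible pre-conditioning count), multiplied
  by lognormal patient-level (σ = 0.35) and observation-level (σ = 0.15)
  noise, sampled daily. The daily median across patients becomes the
  population reference, so the reference reproduces the template's nadir
  (day 8), recovery medians (2.3 at day 20, 4.7 at day 30) and peak
  (day 41) by construction;
* CsA: troughs every 2 days from a two-piece lognormal whose three
  quantiles match the reported marginal exactly (median 178, P5 48.0,
  P95 333.1 ng/mL — those quantiles are asymmetric on the log scale, so a
  plain lognormal cannot match all three), with within-patient correlation
  0.5 via a shared patient-level normal component that leaves the marginal
  invariant;
* event times are drawn from the transit-delay model itself at the
  reference estimates, giving a ~45% crude 100-day event fraction (the
  generated cohort's median CsA of 178 ng/mL sits below the 250 ng/mL
  centring point, raising incidence above the reference patient's 42%).

What the generator does **not** emulate: serial autocorrelation beyond a
patient-level random effect, CsA dose titration over time (levels are
stationary), relapse/death as competing risks, therapy switching (only
generic dropout), and any real-data missingness patterns. Passing tests
therefore demonstrate internal consistency of the estimator/simulator
pair and calibration under the assumed data-generating process — not
predictive performance on clinical data.

## Problem sizes used in the checks

Suite sizes were chosen so each check is decisive at single-CPU scale:
parameter recovery refits one n = 2000 cohort (integration step 0.2 d for
the fit; estimates change by far less than one standard error vs 0.1 d);
stratification ordering uses 200 cohorts of n = 1000; cross validation
uses n = 400 with the base (no-covariate) transit model; survival-sampling
calibration uses 10⁵ draws; VPC self-consistency uses 1000 replicates of
an n = 1109 cohort.

## Known limitations

* The transit-chain length is a reconstruction (n = 7); any n with
  n/k_tr ≈ 11.3 d reproduces the published summaries almost equally well,
  so `n_transit` should not be over-interpreted.
* Exact ML standard errors assume a well-behaved likelihood; for small
  cohorts (< ~200 events) the Wald intervals for the exponents γ_WBC and
  γ_age are noticeably anti-conservative.
* The log-rank-based CV metric is insensitive to incidence-matched shape
  misspecification (see Estimation above).
* Risk ratios are simulation-based contrasts under the fitted model, not
  causal estimates; confounding enters exactly as it does the fit.
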