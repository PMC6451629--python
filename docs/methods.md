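# Methods

`bmicost` implements a complete cost-epidemiology pipeline relating body
mass index (BMI) to annual primary-care service use and costs in a cohort
of women aged 55–79, together with a synthetic-data generator whose
ground truth every stage can be tested against. This note documents the
models, the generator, the numerical choices, and what the tests do and
do not demonstrate.

## Analysis model

**Outcome models.** Annual counts (consultations, prescription items,
tests) and annual costs (GBP) are modelled with quasi-likelihood
log-link GLMs with Poisson-like variance, Var(y) = φ·μ. The
quasi-likelihood score equations are identical for integer counts and
non-negative continuous costs, so one family serves both; no two-part or
gamma model is used. φ is estimated by Pearson X²/(n−p) — the standard
quasi-Poisson choice, and well defined for continuous costs (the
deviance-based estimator is not).

Exposure is either the eight-band fine BMI category (half-open
boundaries `[lower, upper)`, reference 20–<22.5 kg/m²) or, for trends,
continuous BMI restricted to rows with BMI strictly above 20.
Adjusters: age band, region, deprivation third, education, parity, age
at first birth, smoking, alcohol, financial year, and the fraction of
the year with observed data. Missing covariate values form their own
category level (never the reference). The observed fraction enters as a
linear covariate, not an offset; predictions standardize it to 1, which
defines "annual" estimates.

**Cluster-robust variance.** Person-years within a woman are correlated
(she is the independence unit), so all inference uses the sandwich
estimator V = B⁻¹(Σ_g s_g s_g′)B⁻¹ with bread B = X′WX (W = μ for the
log link), cluster scores s_g = Σ_{i∈g} x_i(y_i − μ_i), no dispersion
factor in the meat, and a G/(G−1) small-sample factor. 99% intervals use
the normal quantile 2.5758 throughout (cluster counts are large in
intended use; no t correction).

**Floated (quasi-variance) confidence intervals.** To let readers
compare any two BMI categories, each category k — including the
reference — receives a pseudo-variance v_k chosen so v_i + v_j
approximates Var(λ_i − λ_j) for every pair of category log relative
rates. The objective is the sum of squared *log*-scale errors (scale
free, the standard choice in the quasi-variance literature), minimised
by deterministic least squares on log v with two fixed starts (the
shared-reference decomposition, exact when Cov = v₀ + diag(v_j), and an
equal split) followed by a Nelder–Mead polish that guards against stalls
at the v → 0 boundary. Percentage differences are 100·(e^λ − 1) with
group-specific CIs exp(λ_k ± 2.5758√v_k). Trend CIs use conventional
cluster-robust variances; only category effects are floated.

**Standardization (g-computation).** For each category k, every fitted
person-year keeps its covariates, its BMI category is set to k and the
observed fraction to 1; the standardized annual mean c_k averages the
predictions. The standardization population is the fitted person-years
(not persons), matching the person-year analysis unit. With the log link
and additive category terms this factorises as
c_k = exp(λ_k)·mean(exp(X_ref β)), which the uncertainty path exploits:
CIs come from 10,000 (configurable) multivariate-normal draws of β using
the cluster-robust covariance, percentiles 0.5/99.5 (parameter
simulation rather than the delta method, for internal consistency with
the projection CIs). Mildly indefinite covariances are repaired by
flooring eigenvalues at zero; anything materially indefinite is an
error.

**Projection.** A population table gives millions of women per coarse
BMI band (<25, 25–29.9, 30–34.9, 35–39.9, ≥40; default 2.83, 2.28,
1.06, 0.30, 0.16 — total 6.63 million) with weights allocating each
coarse band across its fine bands. Per-person coarse costs are fine-
weight averages; the reference cost is the weighted average of the
20–<22.5 and 22.5–<25 bands (the 20–24.9 reference). Totals
T_k = N_k·c_k, attributable costs A_k = N_k·(c_k − c_ref) and
proportions P_k = A_k/T_k are reported per band and for the ≥25
aggregate; negative attributable costs are retained, not truncated.
Population counts are fixed (no sampling error); CIs re-project each
parameter draw and take percentiles. Reported percentages round half
away from zero; full precision is kept internally. Prescription costs
are additionally decomposed over 18 therapeutic-use categories (15 BNF
chapters plus analgesics, drugs in diabetes, dressings/appliances), one
cost model per use, with attributable shares over the summed
attribution.

**Diabetes mediation.** The adjusted-difference heuristic: refit the
cost model with the carried-forward diabetes flag added, re-project, and
report E = (P_base − P_adj)/P_base on the ≥25 aggregate attributable
proportion. Because the proportion-based and absolute-cost readings can
differ, the analogous measure on absolute attributable costs is reported
alongside, clearly labelled. This is not a causal natural-effect
decomposition.

**Subgroup heterogeneity.** Inverse-variance χ² on subgroup slopes:
Q = Σ w_j(b_j − b̄)², df = J−1, with cluster-robust variances; subgroups
partition persons and are treated as independent.

## Synthetic-data generator

The generator emulates the data structure of a UK cohort of women aged
55–79 linked to primary-care records; its defaults are the study
conditions the package is calibrated to reproduce.

* **BMI**: a two-component truncated (≥18.5 kg/m²) normal mixture,
  N(24.06, 2.56²) with 41.45% weight on N(28.63, 5.43²), fit to the
  eight-band share pattern of such cohorts with exactly 47% of mass
  below 25 kg/m².
* **Counts**: negative binomial with conditional variance φ·μ
  (φ default 1.5; φ = 1 gives Poisson), mean
  fraction_observed · baseline · exp(slope·max(BMI − 21.25, 0) +
  covariate effects + person frailty) · diabetes multiplier. The
  BMI–log-rate relation is flat below 21.25 (the reference-band
  midpoint) and linear above, so rates are lowest in the reference band
  with a single slope parameter.
* **Frailty**: a person-level log-normal effect (σ default 0.5) creates
  the within-person correlation the sandwich variance must absorb. The
  magnitude of real-world within-person correlation is unknown; 0.5 is
  a free choice reported in `truth.json` and never asserted against
  external values.
* **Diabetes**: annual incident hazard logit(p) = −7.6 + 0.155·BMI,
  carried forward once present (~11% of person-years at defaults);
  diabetes multiplies count means (defaults: consultations ×1.35,
  prescriptions ×1.5) and shifts the prescription mix towards drugs in
  diabetes.
* **Costs** equal counts times unit costs exactly (consultation
  £41.14, test £6.31, per-item prescription costs by therapeutic use
  averaging £8.41), so cost columns are deterministic given counts.
* **Follow-up**: up to 6 years with a 3% annual probability that
  follow-up ends mid-year (uniform partial fraction in the exit year),
  giving ~5.6 observed years per woman; covariates are drawn
  independently of BMI unless the confounding option couples
  deprivation to BMI; missing covariate labels are injected at 2%.

**Calibration.** Baselines and unit costs put the reference-category
annual means at 7.0 consultations (£288), 27.0 items (£227) and 8.4
tests (£53). The direct BMI slopes are solved so the *implied total*
cost trends per 2 kg/m² above 20 — including the diabetes pathway — are
5.2% (consultations), 9.9% (prescriptions) and 0% (tests). The implied
trend is computed exactly in `bmicost.truth` as the root of the
population estimating equations of the misspecified log-linear fit, and
all parameter-recovery tests target these implied truths rather than
the raw slope parameters. Under the default population table the true
excess-weight attributable proportions come to 0.170 (consultation
costs) and 0.299 (prescription costs). A higher prescription target
(~0.31) cannot be combined with the 9.9% trend under this generative
shape without forcing the diabetes multiplier below 1 — the
piecewise-linear relation makes the 22.5–<25 band costlier relative to
the reference than the flat-bottomed pattern seen in real cohorts,
which dilutes the attributable proportion; the package keeps the
scientifically plausible multiplier and accepts 0.299.

**What the generator does not emulate.** Clinical coding (Read/BNF),
staff types, hospital admissions, cost-mix variation within consultation
or test categories (so count and cost trends coincide per outcome),
time-varying age, staggered entry, and the elevated prescription costs
sometimes seen in the 18.5–<20 band (an `underweight_rx_excess`
parameter exists, default 0). Passing tests therefore demonstrate
correctness of the estimators under a faithful structural emulation,
not agreement with any particular real dataset.

## Numerical choices

* IRLS convergence: relative deviance change < 1e-8, max 100 iterations
  (statsmodels); non-convergence and identically-zero responses are
  errors, not warnings.
* Rank deficiency is detected by pivoted QR and reported with the
  offending column names.
* Truth-side integrals use a 4001-point trapezoid grid on BMI ∈
  [18.5, 75]; implied trends use `fsolve` on the two-parameter
  estimating equations (xtol 1e-12).
* All randomness flows from one run seed through named `SeedSequence`
  substreams (simulation vs bootstrap), so changing the number of
  parameter draws never perturbs the simulated data, and every output
  is byte-identical across reruns with the same seed.
* Problem sizes in the test suite are scaled to the structure being
  tested: replicate studies use 100 cohorts of 5,000 women × ≤6 years
  with 500-draw bootstraps; the mediation limit uses ~56,000
  person-years; oracle-equivalence tests use ≤500-row designs.

## Known limitations

* Costs share the count variance function (variance ∝ mean); strongly
  right-skewed cost data may be better served by a gamma or two-part
  model, which is out of scope here.
* The fraction-of-year covariate is linear in the analysis model while
  multiplicative in the generator; predictions at fraction 1 make the
  discrepancy immaterial for ratios (it cancels in percentage
  differences and attributable proportions) but it can shift absolute
  levels by a fraction of a percent.
* Fine-to-coarse population weights default to equal shares within each
  coarse band (or mixture-implied shares when derived from a simulation
  config); real population surveys would supply their own weights via
  `population.csv`.
* The mediation measure is descriptive; it inherits all the caveats of
  conditioning on a post-exposure variable.
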