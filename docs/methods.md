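# Methods

`ceamiss` implements and compares six strategies for handling missing cost
and health-utility data in a within-trial cost-effectiveness analysis, and a
synthetic-trial generator that reproduces the missingness regime those
strategies were designed for: a two-arm trial with staggered recruitment, a
fixed calendar study end, dense follow-up in year 1 and a single late
telephone follow-up per patient.

## The data model

A trial records, per patient: baseline covariates (treatment arm `TREAT`,
`AGE` in years, ulcer `SIZE` in cm², ulcer `DURATION` in years, `SITE` as a
factor, plus inert binaries — ethnicity, diabetes, DVT history, trial leg —
carried only as imputation predictors), a recruitment offset, and two
longitudinal outcome streams:

* **period costs** `Y_it` (GBP): 12 roughly-monthly periods over year 1
  (boundaries at weeks 0, 4, 8, 13, 17, 22, 26, 30, 35, 39, 43, 48, 52),
  then yearly periods to weeks 104, 156, 208, 260;
* **EQ-5D utility** at weeks 0, 6, 26, 52 and at most one late week from
  {104, 156, 208, 260}.

Both streams follow a linear model with a time factor, a treatment-by-time
interaction δ_t (the object of inference), common baseline-covariate
effects, a shared per-patient random intercept ς_i and independent
residuals. Costs are floored at zero after noise (the floor rate is logged);
utilities are clipped to [−0.594, 1]. Deaths (off by default) zero both
streams thereafter while keeping them *observed*.

### Missingness layers

1. **Structural (deterministic given recruitment date).** With recruitment
   uniform over 36 months and the study closing 65 months after the first
   recruit, follow-up spans 29–65 months. Cost periods ending after the
   censoring week are missing by design; of the post-year-1 EQ-5D weeks the
   patient keeps only the *latest grid week within follow-up* — the
   telephone call. A degenerate `telephone=False` switch disables the
   pruning for pass-through testing.
2. **Stochastic MAR.** Each remaining item goes missing with probability
   `expit` of a logistic index in treatment, centred baseline covariates,
   site, a week factor and (optionally) the most recent *observed* utility
   — the last term makes the mechanism depend on outcome history, which is
   what separates complete-case analysis from imputation in the bias
   demonstration. Week-0 EQ-5D is never missing (it doubles as the baseline
   covariate `eq5d0`).

Defaults: EQ-5D item missingness ≈ 10% at week 6 rising to ≈ 25% at the
telephone week with a mild age and site gradient; cost items ≈ 5%; no
outcome-history term. True effects default to δ_t^C = 0 (no cost effect)
and a constant utility effect 0.07·52/153 ≈ 0.0238, chosen so the
undiscounted 3-year incremental QALY is exactly 0.07. The pre-missingness
truth is retained in shadow tables used only for scoring recovery.

What the generator does **not** emulate: skewed cost distributions (costs
are conditionally normal, floored), non-uniform accrual, item-level EQ-5D
responses (utilities enter as already-valued indices), and deaths by
default. Passing tests therefore show correctness of the estimators under a
normal, MAR world — not robustness to skewness or informative missingness.

## Shared outcome aggregation

Discounting (3.5%/year by default) assigns each cost period and each
utility segment the factor `(1+r)^-y` with `y` the completed years at the
interval midpoint; year-1 items are undiscounted. Per-patient totals at a
horizon T ∈ {1, 3, 5} years are the discounted sum of period costs and the
discounted trapezium ("area under the curve") of utilities. Both totals are
missing unless every constituent up to T is observed; for QALYs the
constituents are the patient's *scheduled* weeks, and the horizon week
itself must be scheduled — so at 3 years only patients whose telephone call
landed on week 156 can be complete, which reproduces the sharp loss of
complete cases the comparison turns on. QALYs are discounted like costs by
default (`discount_qalys=False` restores a costs-only reading). Custom
grids without a point at the horizon are truncated at the boundary by
linear interpolation.

## The six estimators

* **CCA** — bivariate normal regression of (total cost, total QALY) on
  `eq5d0`, `TREAT`, `DURATION`, `AGE`, `SIZE` and site dummies, on complete
  cases only. With shared regressors the SUR estimator equals per-equation
  least squares; the joint covariance is `Σ̂ ⊗ (X'X)⁻¹`, giving the
  parametric CEAC. Factor levels empty in the complete-case subsample are
  dropped; genuine collinearity raises with the aliased columns named.
* **RMM / RMFE** — the repeated-measures model on all observed items, with
  baseline (week 0) as the interaction reference. RMM treats ς_i as a
  random intercept, fitted by profiled REML: the marginal covariance is
  `σ²(I + ρJ)` per subject, so GLS reduces to partial demeaning and the
  criterion is a 1-D search over log ρ (ML available by flag). RMFE is the
  within estimator — exact LSDV — with a cluster-robust covariance; the
  treatment main effect and all time-invariant covariates are absorbed. The
  cost models include week-0 rows with Y ≡ 0; without them the within
  estimator could not identify absolute per-period treatment differences
  (the interaction columns would sum to the absorbed main effect).
  Incremental totals are linear combinations of coefficients — a discounted
  sum of δ̂_t for costs, a discounted trapezium of the arm-difference
  profile (β̂₁ at baseline, β̂₁+δ̂_w at week w; β₁ ≡ 0 under RMFE by
  randomisation) for QALYs — with delta-method variances. Joint (ΔC, ΔQ)
  uncertainty comes from a patient-level bootstrap, stratified by arm and
  clustered by patient, refitting both outcome models on each replicate (B
  defaults to 1000; failed replicates are redrawn and counted, > 5% aborts).
* **MILR / MIPMM** — chained-equations multiple imputation over all 24
  longitudinal variables (16 period costs, 8 EQ-5D weeks) in schedule
  order, each regressed on the other 23 plus the baseline predictors.
  `linreg` draws the residual variance from its scaled inverse-χ²
  posterior, coefficients from their conditional normal, then adds residual
  noise (proper imputation). `pmm` uses type-2 matching: posterior-draw
  predictions for missing cases, least-squares predictions for donors, a
  uniform draw among the k = 10 nearest (ties at the k-th distance enlarge
  the pool). Cells missing by design *are* imputed — that is how MI reaches
  horizons beyond a patient's own follow-up. Defaults M = 40, 20 cycles;
  per-imputation seeds are spawned from the master seed. Totals are then
  computed passively and the bivariate regression is pooled by Rubin's
  rules with Barnard–Rubin degrees of freedom, FMI, the Monte-Carlo error
  `√(B/M)` and the efficiency loss FMI/M.
* **BPA** — a Bayesian selection model on the aggregate totals of all
  patients: (cost, QALY) bivariate normal given the CCA regressors, every
  missing total a parameter drawn from its conditional normal given the
  observed partner outcome, and logistic submodels of the two missingness
  indicators (with follow-up length as an extra predictor) sampled
  alongside by random-walk Metropolis. Under MAR with distinct priors the
  outcome inference is ignorable; a switch drops the submodels so the
  ignorability can be verified empirically. Sampling is conjugate Gibbs for
  coefficients (normal prior, precision 0.001 by default), missing totals
  and the residual covariance (inverse-Wishart, df 3, scale 0.01·I).
  Coefficient priors act on an internally standardised outcome scale —
  costs in GBP would otherwise be shrunk drastically by a precision of
  0.001 — which keeps the stated 0.001–0.01 sensitivity range vague, and
  the alternative reading (a gamma hyperprior on the residual precision) is
  then immaterial. Defaults: 2 chains × 10,000 iterations, 2,000 burn-in;
  split-chain R̂ > 1.05 raises with per-chain trace summaries.

## Decision layer

`icer` returns ΔC/ΔQ or a dominance label (never a signed ratio for a
dominant/dominated quadrant). The CEAC is
`Φ((λμ_Q − μ_C)/√(λ²σ²_Q − 2λσ_CQ + σ²_C))` parametrically, or the
positive-net-benefit fraction of draws; the λ grid is 0–£50,000 in £500
steps. `compare_methods` runs any subset of methods × horizons from one
master seed (cell seeds spawned deterministically), records per-cell
failures without aborting, and emits the summary table, long-format CEAC
and pattern tables. Confidence intervals are normal-theory for the
parametric methods and percentile for the bootstrap-backed ones.

## Numerical choices and problem sizes

Rank deficiency anywhere is handled by pivoted-QR column dropping (logged
or raised, as noted above). The MCMC convergence diagnostics (split-chain
R̂, initial-positive-sequence ESS) are computed in-package. Test-suite and
acceptance runs scale the expensive pieces down as their own study design:
M = 10 imputations × 5 cycles and 2 × 1,500 MCMC iterations inside the
25-trial recovery study, M = 40 × 20 for the stability diagnostics,
B = 300–500 bootstrap replicates; these sizes leave the Monte-Carlo error
well below the tolerances being asserted.

Known limitations: no multilevel (site-clustered) imputation; no MNAR
sensitivity models; no bootstrap-within-MI; no random site effects in the
Bayesian model; no half-cycle correction or continuous-time discounting;
cost skewness is not modelled. The minimum follow-up implied by the
recruitment window (29 months) intentionally exceeds the nominal 1-year
minimum sometimes quoted for such designs — the window and study end are
taken as given and not reconciled.
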