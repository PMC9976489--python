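# Methods

This note documents the models implemented in `methclock`, the synthetic
data they are exercised on, the numerical choices that affect results, and
the limits of what the tests demonstrate.

## Synthetic cohorts

The generator (`methclock.simulate`) works on the M-value scale and derives
beta values exactly through the logistic inverse, so the two scales used
downstream (M-values for association testing, betas for clocks and
EpiScores) are linked by construction rather than approximated.

Each CpG belongs to exactly one class:

* **linear** — M = a + b·age, slope b ~ N(0, `effect_size_sd`) per year;
* **quadratic** — M = a + b·age + c·age², with c scaled by the half age
  span so the curvature term's spread is comparable to a linear CpG's;
* **logage** — M = a + b·log(age), with b variance-matched to the linear
  class over the age range; this mimics loci that change rapidly in early
  life and stabilise in adulthood;
* **smoking** — M = a + s·pack_years;
* **null** — intercept only.

On top of the class signal every CpG receives a per-(batch, CpG) offset
~ N(0, `batch_sd`) and i.i.d. noise ~ N(0, `noise_sd`); betas are clipped
to (0.001, 0.999) so no value moves by more than 0.001.

Ages are uniform on `age_range`.  A uniform distribution (rather than an
empirical cohort age histogram) keeps the power of the age EWAS analytic:
for a linear CpG the squared age–CpG correlation is
ρ² = b²·Var(age) / (b²·Var(age) + σ²), and the EWAS t-test is noncentral
F(1, n−2) with ncp = n·ρ²/(1−ρ²), which `linear_power_oracle` evaluates
per simulated slope.  The effect map (class assignment, slopes, EpiScore
weights) is drawn from `effect_seed`, separate from the sampling seed, so
several cohorts can share one age–methylation map — the condition under
which leave-one-cohort-out evaluation is meaningful — while a cohort with
a different `effect_seed` serves as a distribution-shifted test case.
Effect-map scalings use the theoretical moments of U(lo, hi), not sample
moments, so the map is identical across cohorts regardless of which ages
they drew.

**Survival** follows a Weibull-baseline proportional-hazards model:
h(t) = (k/s)(t/s)^{k−1}·exp(η) with η = `log_hr_age`·(age − mean age) +
Σ_p loghr_p · z(score_p), inverted exactly to draw event times, with
administrative censoring only (censor-at-last-update design; no competing
risks).  The proteins named in `episcore_log_hrs` get latent per-sample
levels ~ N(0,1) that shift their panel CpGs' M-values by
`protein_signal_sd` × weight per SD.  Without this component an EpiScore
would be a pure noise/age combination, and any score whose random CpG
subset contained a single age-CpG would collapse into an age proxy
(observed |r| with age up to 0.9 on small simulated genomes), making the
survival-driving proteins unidentifiable; the latent levels give each
score protein-specific variance, as real protein EpiScores have.

Defaults, chosen once: age range [18, 99] years (adult recruitment span),
`effect_size_sd` 0.02 M-units/year and `noise_sd` 0.1 (power neither 0 nor
1 at desk-scale n), `batch_sd` 0.05, Weibull shape 1.3 and scale 40 y with
`log_hr_age` 0.09/yr (mortality roughly doubling per decade) and
censoring at 14 y (≈25–35% events in an adult cohort).

**What the generator does not emulate**: array-level artifacts (probe
cross-hybridization, dye bias, detection failures), cell-composition
effects on methylation (cell proportions are simulated as Dirichlet
covariates but do not feed the CpG values), family/kinship structure, and
non-uniform age distributions.  Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under the stated
generative model — not robustness to the artifacts of real arrays.

## Age EWAS

The outcome orientation is age regressed on the CpG (Age ~ CpG and
Age ~ CpG + CpG²), with age mean-centred and CpG / CpG² M-value columns
scaled to mean 0, variance 1 (sample sd, n−1).  This orientation affects
the standard errors and is deliberate; note its consequence: a perfectly
age-symmetric CpG (M ∝ (age−mean)²) carries no linear-regression
information about age — what the quadratic term detects is curvature of
monotone trajectories, and the test suite encodes exactly that.

For speed at many CpGs the covariates (sex, batch/set dummies, smoking
dummies with never as reference and unknown as its own level, pack years,
cell proportions with one column dropped, optional DNAm PCs) are projected
out once: age and all CpG columns are residualized on the covariate design
through a QR-based annihilator, after which each per-CpG fit is a one- or
two-variable regression solved in closed form with residual degrees of
freedom n − q − 1 (or − 2).  Frisch–Waugh–Lovell equivalence with the full
design is asserted in the tests at 1e-8.  CpGs that are constant or
numerically collinear with the covariates are flagged with missing results
rather than raising.  DNAm PCs are the top left singular directions scaled
by singular values, computed on standardized M-values of up to 20,000 most
variable CpGs to bound memory.

The nested F-test uses the RSS identity F = (RSS₁−RSS₂)/(RSS₂/df₂) with
p from F(1, df₂); the per-CpG linear t² equals the F against the
covariate-only model, which the suite verifies.

## Cox engine

A single Newton–Raphson maximizer of the Breslow-ties partial likelihood
backs the mortality EWAS, the association tests and the PH diagnostics:
risk-set sums are reverse cumulative sums over time-sorted samples
(vectorized), the linear predictor is shifted by its maximum before
exponentiation (the shift cancels exactly in the partial likelihood),
steps are halved whenever the likelihood would decrease, and convergence
is max |score| < 1e-8 within 50 iterations.  Constant CpGs are flagged
degenerate (HR 1, p 1); non-convergent fits (monotone likelihood) are
flagged rather than raised.  Efron tie handling is not implemented;
against lifelines the fits agree to ~1e-5 without ties and differ at the
third decimal with ties, as expected for Breslow vs Efron.

Schoenfeld residuals are the event-time covariate deviations from the
risk-set mean; at the optimum they sum to zero per covariate (score
equation), asserted at 1e-6.  The proportional-hazards test is the
Grambsch–Therneau score test on scaled residuals against a transform of
event time — Kaplan–Meier (1 − S(t−)) by default, identity and rank by
option — with per-variable χ²₁ statistics and a global χ²_p combining
covariates through the inverse information.  Its null level is verified by
Monte Carlo (5.0–5.5% at nominal 5% in the suite's 200-run checks).

## Elastic nets

**Gaussian.**  Objective (1/2n)‖y − b₀ − Xb‖² + λ(α‖b‖₁ + (1−α)/2‖b‖₂²).
Features are standardized internally with n-denominator sds and
coefficients returned on the original scale with adjusted intercept, so
exported weight tables are reproducible.  The solver is covariance-form
cyclic coordinate descent: G = XᵀX/n and the gradient vector are
maintained incrementally (O(p) per update, with G shared across the whole
λ path), with warm starts down a descending grid (default 100 log-spaced
points from λ_max = max|xⱼᵀy|/(nα) to 10⁻³λ_max), active-set cycling and
a confirming full sweep.  Internally the outcome is scaled to unit
variance — the L1 weight is divided by sd(y) and coefficients multiplied
back, an exact reparametrisation — so the convergence tolerance
(max |Δb| < 1e-7) is scale-free.  Because methylation designs are highly
correlated and plain coordinate descent converges slowly there, each λ
additionally attempts a feature-sign refinement: solve the stationarity
system (G_AA + λ(1−α)I) b_A = c_A − λα·sign(b_A) on the current active
set, drop sign-inconsistent features, admit the worst inactive KKT
violator, and repeat; on success the solution is exact to solver
precision.  KKT conditions (|xⱼᵀr/n − λ(1−α)bⱼ| ≤ λα for zeros, equality
with sign for non-zeros) are exposed via `check_kkt` and asserted across
whole paths at 1e-6 (observed ~1e-14).  λ is selected by the minimum mean
cross-validated MSE (minimum rule, not 1-SE), over folds built by
`make_folds`: groups (e.g. technical batches) are shuffled with the seed,
then greedily assigned in decreasing-size order to the smallest fold, so
grouped samples never split and fold sizes differ by at most the largest
group.

**Cox.**  Objective −(1/n)·Breslow log partial likelihood + the same
penalty; no intercept (absorbed into the baseline hazard).  Outer
iteratively reweighted least squares with the exact diagonal Hessian
weights wᵢ = μᵢ − exp(2ηᵢ)·H₂(tᵢ) and working response z = η + (δ−μ)/w,
inner weighted coordinate descent, step-halving on the penalized partial
likelihood (never allowed to decrease), at most 25 outer iterations per λ.
λ maximizes the mean held-out Harrell's C across grouped folds; a fold
with zero events is an error.  The α→0 limit agrees with an independent
quasi-Newton solve of the smooth ridge objective at 1e-5, and KKT
certificates use the gradient of the negative mean partial likelihood.

**Pre-selection.**  Features for the cAge clock are the top `n_linear`
CpGs by ascending linear p-value (β scale) plus the top `n_quadratic` by
ascending quadratic-term p-value (β² scale); each squared CpG absent from
the linear set is also added in linear form.  Ties break lexicographically
by CpG id.  Both linear and squared features enter on the beta-value
scale (squared terms are explicitly beta-scale; linear terms follow for
consistency).

## Clocks

`train_cage` pools cohorts, builds the β/β² design, and fits two nets on
the same features — outcome age and outcome ln(age).  Prediction applies
the hybrid rule: the age model's output is kept unless it is **20.0 years
or younger (inclusive)**, in which case exp(log-model output) replaces it;
no smearing/bias correction is applied to the exponentiated prediction.
Missing model CpGs are a hard error — silent zero-filling would change
predictions invisibly.  Models serialize as weight tables (feature,
transform, weight + `(Intercept)` row) with metadata headers carrying the
outcome transform, α, selected λ and the sex coding (female=1/male=0).

`train_bage` z-scores every input feature within the training dataset
(n−1 sd) and keeps the non-zero-weight features of the C-selected Cox
net.  `compute_bage` applies the standardization contract: features
z-scored within the scoring dataset, linear predictor z-scored within the
dataset (mean 0, sd 1 at 1e-10) — bAge is a cohort-relative score, and a
single new sample cannot be scored in isolation by design.  `compute_age_accel`
is the simple-OLS residual of the prediction on age, orthogonal to age and
the constant by the normal equations.

## Evaluation

* `regression_metrics`: Pearson r, RMSE, and MAE = **median** absolute
  error, with the mean absolute error under `mean_abs_error`.
* `harrells_c`: a pair is comparable when the earlier time is an event
  (ties with a censored later sample included); concordant when the
  earlier-failing sample has the higher score; score ties count ½.
  Agrees with scikit-survival's estimator to 1e-12 and is invariant under
  strictly increasing score transforms.
* `cox_association`: the acceleration score is z-scored within the
  dataset (HR per SD), modelled with age and sex (plus optional joint
  covariates); Wald CIs, matching standard survival-package reporting.
* `fixed_effects_meta`: inverse-variance pooling, pooled SE = (Σ sᵢ⁻²)^{−½}.
* `loco_harness`: trains on all cohorts but one, predicts the held-out
  cohort, logs provenance proving the held-out cohort never entered
  training, and pools held-out predictions for combined metrics.  An
  `anchor_cohort` can be pinned to training in every round (the design in
  which the largest cohort is never held out).

## Problem sizes used in the checked runs

The packaged test suite and `scripts/acceptance.py` run everything at desk
scale, chosen up front: EWAS calibration on 500–1000 null CpGs at n =
400–500; the cAge pipeline on one 2000 × 5000 training cohort with 200
planted clock CpGs, 500+50 pre-selected features, 5 batch-grouped folds
and a 30-point λ grid, evaluated on a held-out 800-sample cohort; bAge on
20 (suite) or 10 (script) simulations of n = 2000 with ~200 events, 20
proteins (3 causal at 0.5 log-HR/SD), 5 folds and a 20-point grid; null
coverage and PH calibration over 200 Monte-Carlo replicates.  The CLI
defaults (25-fold cAge CV, 20-fold bAge CV, 100-point grids, 10,000+300
pre-selection) reflect full-scale practice.

## Known limitations

* Breslow ties only; Efron would be preferable with heavy tie structure.
* The PH test uses the averaged-information approximation of the
  Grambsch–Therneau statistic; its level is verified empirically, not
  exactly.
* Elastic-net paths are not guaranteed monotone in the number of selected
  features (violations are rare and tolerated in the tests).
* The noise floor used to judge cAge accuracy counts only the linear
  clock CpGs' information and treats age as Gaussian; it is a bound for
  test purposes, not an exact minimax quantity.
* bAge scoring is cohort-relative by contract; cross-cohort calibration
  of absolute risk is out of scope.
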