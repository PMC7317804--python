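# Methods

## Model

`jointtraj` couples a Gaussian linear mixed model for a longitudinal
biomarker with a Weibull proportional-hazards model for an event time,
linked through shared random effects.

**Longitudinal submodel.** On the chosen scale (log2 µg/mL by default),
subject *i*'s latent trajectory is linear in follow-up time,
m_i(t) = (β₀ + b₀ᵢ) + (β₁ + b₁ᵢ)·t + xᵢ'γ_L, with subject effects
bᵢ = (b₀ᵢ, b₁ᵢ) ~ N(0, D), D unstructured (intercept–slope correlation
free), and measurement error εᵢⱼ ~ N(0, σ²). Log2 is the default scale
because D-dimer is strongly right-skewed and the association parameter then
reads "per doubling"; the natural-log and raw-µg/mL scales are supported,
with the exact reparameterization identity α_log2 = α_ln·ln 2 verified in
the test suite.

**Event submodel.** hᵢ(t) = λ·p·t^(p−1)·exp(wᵢ'γ_S + α·mᵢ(t)), i.e. a
Weibull baseline hazard (h₀(t) = λ p t^{p−1}) modulated by baseline
covariates and by the *current value* of the latent trajectory. Options:
an additional first-derivative association α_d·(β₁ + b₁ᵢ) (does the rate of
biomarker change carry information beyond its level?), and an
association × covariate interaction giving per-stratum α. Competing deaths
are right-censoring events in this submodel — a deliberate simplification
(see Limitations).

**Likelihood.** Each subject contributes
log ∫ p(y_i | b) · h_i(T_i)^{δ_i} exp(−∫₀^{T_i} h_i) · φ(b; 0, D) db.
The 2-D random-effects integral uses *adaptive* Gauss–Hermite quadrature:
a damped Newton iteration (the integrand is log-concave, so this is safe)
finds each subject's conditional mode and curvature at every parameter
value, and the tensor-product Hermite grid (default 9 nodes per dimension)
is recentred and rescaled there. The inner cumulative hazard uses
Gauss–Legendre quadrature (default 15 nodes) after the substitution
u = s^p, which integrates the Weibull baseline factor exactly, removes the
t^{p−1} endpoint singularity, and makes the α = 0 separability identity
(joint log-likelihood = mixed-model + Weibull log-likelihoods) hold to
machine precision. Doubling either node count changes the log-likelihood by
< 1e−4 on test cohorts, and the quadrature matches a 100,000-draw
Monte-Carlo oracle within its MC error.

**Estimation.** Variance parameters are optimized on unconstrained
transforms (log-Cholesky for D, log for σ, λ, p). Starting values come from
the standalone mixed-model and Weibull fits with α = 0. L-BFGS-B maximizes
the likelihood, followed by one or two Newton steps using the
finite-difference observed information — this "polish" pins the optimum
tightly enough that reparameterization invariances (days↔months,
log2↔natural log) hold to ~1e−9 in α. Standard errors are the inverse
observed information (central differences, relative step 1e−5); Wald
intervals and p-values follow. AIC = 2k − 2·loglik with k the full free
parameter count. `compare_fits` refuses to rank fits across outcome
transformations unless the caller asserts the Jacobian has been handled,
because log-scale and raw-scale likelihoods are not comparable as printed.

## Surrounding estimators

* **Kaplan–Meier / Aalen–Johansen** are implemented directly (and
  cross-checked against lifelines in the tests): the spec-level guarantees
  we wanted — events-before-censoring tie handling, a single risk-set
  update for simultaneous different-cause ties, CIF_VTE + CIF_death +
  S_all-cause = 1 to 1e−12, and log(−log)-scale pointwise bands for both
  curves (Greenwood variance for KM, Marubini–Valsecchi for the CIF) — are
  not all exposed by existing implementations. 1−KM treats competing
  deaths as censoring and therefore *over*states incidence; the dominance
  1−KM ≥ CIF is asserted in tests.
* **Weibull PH regression** is a direct ML fit of the closed-form censored
  likelihood, with covariates centred for stability, optional fixed shape
  (p = 1 reduces exactly to exponential regression, whose no-covariate MLE
  events/follow-up is a test oracle, and which is likelihood-equivalent to
  a Poisson GLM with log-time offset — a second oracle), and per-5-unit /
  per-doubling covariate transforms.
* **Mixed models** go through statsmodels' MixedLM with `reml=False`:
  ML, not REML, because fixed-effect structures are compared by AIC.
  The fitted log-likelihood is validated against a stacked
  multivariate-normal oracle at 1e−6. Grouping trajectories by prospective
  event status (group × time interaction) conditions on the future and is a
  descriptive device; the joint model is the inferential product.

## Dynamic prediction

For a subject event-free at landmark s with history y(≤s), the conditional
risk at horizon u is risk(u) = 1 − E[S_i(u|b,θ) / S_i(s|b,θ)]. Default
Monte-Carlo scheme (500 draws): θ from its asymptotic normal on the
unconstrained scale (so positivity constraints cannot be violated), b from
a normal approximation at the subject's empirical-Bayes mode — the
maximizer of longitudinal terms + survival-to-s term + prior, found by the
same Newton iteration as the fitting engine. An exact random-walk
Metropolis sampler for b is available (`sampler="metropolis"`); on test
subjects it agrees with the normal approximation to well under the MC
band width, which is why the faster approximation is the default. The 95%
band is the percentile band of per-draw risks. The survival-to-s term
matters: it pulls the inferred slope *down* relative to a longitudinal-only
empirical-Bayes mode when α > 0 (having survived is evidence against a
steep latent rise); this sign property is tested. Predictions ignore
competing death and are therefore slightly conservative (high).

## Synthetic-data generator

The generator *is* the study conditions, not a tuning knob. Defaults:

| parameter | default | rationale |
|---|---|---|
| n_subjects | 167 | study cohort size |
| visit schedule | every 30 days, jitter SD 2 d, ≤7 visits | "monthly" visits, baseline + 6 follow-ups |
| max follow-up | 250 days | administrative censoring horizon |
| β₀ | log2(0.97) | baseline median 0.97 µg/mL |
| β₁ | 0 | flat population-average trajectory |
| D | diag(1.2², 0.01²) (log2 units; slope per day) | intercept SD matching the observed IQR once σ is added; slope SD chosen so trajectory divergence over 250 d spans the observed spread |
| σ | 0.4 (log2) | within-subject noise assumption |
| α | 1.0225 per doubling | HR e^α = 2.78 |
| Weibull | p = 1, λ = 1.7e−4/day | calibrated (once, by large-n simulation) to ≈12% 250-day VTE incidence under the α-induced frailty; 1.4e−4 without competing death |
| death hazard | 9.6e−4/day constant | calibrated to ≈20% 250-day mortality; constant because no death model is specified anywhere |
| missingness | 1% per visit, MCAR | observed missingness rate |

"Month" is fixed at 30 days for every unit conversion. Event times are
drawn by inverting the subject-specific cumulative hazard against a unit
exponential draw — bracketing + bisection on [0, 250] to 1e−6 days, with
the hazard integral by 64-node Gauss–Legendre in u = s^p (validated against
a 0.01-day trapezoid-grid oracle to <0.1 day). Subjects whose total hazard
on the window falls below the exponential draw are administratively
censored. The measurement-error magnitude and random-effect covariance are
*assumptions* calibrated only to marginal summaries; real cohorts also
contain features the generator deliberately omits — treatment courses,
intercurrent infections, remission status, non-linear trajectories,
informative visit timing. Passing tests therefore demonstrate that the
estimators recover the truth *under the model's own assumptions*, not that
the model is correct for any particular clinical population.

## Preprocessing rules

Patients with any D-dimer measurement above 40 µg/mL are excluded whole
(per patient, not per visit — extreme values of that magnitude destabilize
joint-model convergence); values below 0.1 µg/mL are floored before the log
transform so log2 values stay finite (the floor matters only below any
plausibly reported value); time is stored in days and converted to 30-day
months exactly once, here. Orphan visits and negative biomarker values are
hard errors; `build_dataset` is idempotent.

## Numerical choices and degenerate inputs

* Exponent clipping at e^600 inside the likelihood prevents overflow at
  absurd trial parameters; a non-finite subject contribution raises an
  error naming the subject.
* The starting D for the joint fit is pushed strictly inside the PD cone
  (diagonal floors, correlation clipped to |ρ| ≤ 0.99).
* Mixed-model optimizers are tried in sequence (lbfgs, bfgs, powell),
  keeping the best log-likelihood; a singular fitted D triggers a boundary
  warning, not an error.
* A joint fit that fails the gradient/step criteria returns a partial fit
  with `converged=False` and the optimizer trace; `predict_risk` refuses
  such fits unless forced.
* Ties in the incidence estimators: events before censorings;
  different-cause same-time events share one risk-set update.
* All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning; equal config + seed reproduces
  byte-identical pipeline outputs.

## Test-suite problem sizes

Statistical checks are sized to run on one CPU in a few minutes while
keeping Monte-Carlo error well inside the asserted tolerances: 20
replicates × n = 500 for joint-model HR recovery; 50 small-cohort
replicates for the null-association and confounder-adjustment properties
(n = 100/80, 5-node adaptive quadrature — adequate since adaptivity does
most of the work at these sizes); 200 replicates for mixed-model contrast
coverage; 200,000 subjects for the competing-risk benchmark; 1,000
subjects for prediction calibration-in-the-large (at the true generating
parameters, isolating the prediction machinery from estimation noise).

## Known limitations

* No competing-risk joint model: death is censoring in the event submodel,
  so trajectory-conditional predictions overstate absolute VTE risk when
  pre-VTE mortality is substantial.
* Linear latent trajectories only (polynomial time enters the mixed model
  solely for AIC sensitivity checks).
* Wald inference throughout; profile or bootstrap intervals are not
  implemented.
* The dynamic-prediction default uses a normal approximation to the
  random-effect posterior; the Metropolis option is exact but slower.
* The Khorana score is consumed as an integer covariate; its derivation
  from components is out of scope.
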