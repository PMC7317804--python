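# jointtraj

Joint models of longitudinal biomarker trajectories and time-to-event
outcomes, with dynamic individualized risk prediction.

## The problem

In patients with active cancer, circulating D-dimer — a fibrin-degradation
product marking coagulation activation — is one of the strongest known risk
factors for venous thromboembolism (VTE). A single baseline measurement,
however, is only a snapshot: D-dimer fluctuates over a patient's journey,
and naive summaries of repeated measurements are distorted by informative
drop-out (patients with high D-dimer thrombose or die and leave the cohort,
so the surviving population looks progressively healthier). `jointtraj`
implements the analysis that handles this correctly: a **joint model of
longitudinal and time-to-event data**, plus the surrounding estimators a
full analysis needs, and an honest synthetic-cohort generator so the whole
workflow is testable end to end without patient data.

## The model

For subject *i* with repeated log2 D-dimer measurements *y<sub>ij</sub>* at
times *t<sub>ij</sub>*:

* **Longitudinal submodel** (random intercept and slope, unstructured
  covariance):

  y_ij = m_i(t_ij) + e_ij,&nbsp;&nbsp; m_i(t) = (b0 + b0_i) + (b1 + b1_i) t + x_i'g_L,
  &nbsp;&nbsp;(b0_i, b1_i) ~ N(0, D),&nbsp; e_ij ~ N(0, s²)

* **Event submodel** (Weibull proportional hazards with the *current value*
  of the latent trajectory on the log hazard):

  h_i(t) = lam · p · t^(p−1) · exp( w_i'g_S + **α** · m_i(t) )

The association parameter **α** is the target of inference: exp(α) is the
hazard ratio per one unit of the latent trajectory — per *doubling* of
D-dimer when the trajectory is on the log2 scale. The marginal likelihood
integrates the shared random effects by adaptive (mode-recentred) 2-D
Gauss–Hermite quadrature, with the cumulative hazard by Gauss–Legendre
quadrature in u = t^p. A first-derivative association term and
covariate-specific (per-stratum) α are available as sensitivity options.

Around the core model the package provides:

* competing-risk cumulative incidence (Aalen–Johansen) and 1−Kaplan–Meier,
  with log(−log)-scale pointwise bands;
* maximum-likelihood Weibull proportional-hazards regression on baseline
  covariates (per-5-unit and per-doubling transforms, fixable shape);
* ML linear mixed models with event-group × time interactions, slope
  contrasts, and per-month percent-change back-transforms;
* dynamic prediction: P(VTE ≤ u | event-free at s, biomarker history),
  with Monte-Carlo bands over parameter and random-effect uncertainty;
* a synthetic-cohort generator whose defaults emulate a 167-patient
  oncology cohort (≈12% 250-day VTE incidence, ≈20% mortality, lognormal
  baseline D-dimer with median ≈0.97 µg/mL), and a full
  simulate→preprocess→fit→predict pipeline with a thin `jointtraj` CLI.

## Worked example

```python
import jointtraj as jt
from jointtraj.jointmodel import JointModelSpec

patients, visits = jt.simulate_cohort(jt.paper_like_params(seed=4))
data = jt.build_dataset(visits, patients, time_unit="months")   # 40 µg/mL cap, LOD floor
fit = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
print(fit.hazard_ratio)
```

Running `examples/04_joint_model.py` (which does exactly this) prints:

```
alpha = 1.197 (SE 0.164)
HR per doubling = 3.31 (95% CI 2.40-4.57), p = 3e-13
loglik = -1067.2, AIC = 2152.4, converged = True
```

The generating truth for this cohort is α = 1.0225 (HR per doubling 2.78);
the single-cohort estimate 3.31 sits about one standard error above it, and
averaging over replicate cohorts recovers the truth (see the tests). The
other scripts in `examples/` walk through cohort simulation, per-group
trajectory slopes, competing-risk incidence (CIF 12.2% vs 1−KM 13.2% at the
calibrated rates — the competing-death bias made visible), dynamic
prediction (a stable history → 8.9% six-month risk; a rising history →
52.6%), and the end-to-end pipeline.

## Limitations

Competing death is handled in the incidence estimators but deliberately
*not* in the event submodel or the predictions (the VTE hazard censors
deaths), so predicted risks are slightly conservative in populations with
appreciable pre-VTE mortality. Estimation is maximum likelihood with Wald
inference; no Bayesian machinery, no competing-risk joint model, no
landmarking comparison. See `docs/methods.md` for the full methods note.
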