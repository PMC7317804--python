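"""Fit the joint longitudinal / time-to-VTE model.

The association parameter alpha links the current value of the latent
log2 D-dimer trajectory to the log hazard of VTE: exp(alpha) is the hazard
ratio per doubling of D-dimer at any time of follow-up.
"""

import warnings

import jointtraj as jt
from jointtraj.jointmodel import JointModelSpec

warnings.simplefilter("ignore")

patients, visits = jt.simulate_cohort(jt.paper_like_params(seed=4))
data = jt.build_dataset(visits, patients, time_unit="months")
if data.exclusions:
    print("excluded:", data.exclusions)

fit = jt.fit_joint_model(data, JointModelSpec(scale="log2"))
hr, lo, hi = fit.hazard_ratio
print(f"alpha = {fit.params.alpha:.3f} (SE {fit.ses['alpha']:.3f})")
print(f"HR per doubling = {hr:.2f} (95% CI {lo:.2f}-{hi:.2f}), p = {fit.alpha_pvalue():.2g}")
print(f"loglik = {fit.loglik:.1f}, AIC = {fit.aic:.1f}, converged = {fit.converged}")

# original-scale specification for comparison (per 1 ug/mL increase)
fit_orig = jt.fit_joint_model(data, JointModelSpec(scale="original_ugml"))
table = jt.compare_fits([fit, fit_orig], labels=["log2", "original"],
                        allow_scale_mix=True)
print("\nAIC comparison across biomarker scales (Jacobian not applied — "
      "direction only):")
print(table[["model", "k", "loglik", "aic", "delta_aic"]].to_string(index=False))
print(
    "\nAn HR per doubling well above 1 (the generator uses 2.78) means a "
    "doubling of circulating D-dimer at any time carries a proportional "
    "jump in VTE hazard."
)
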