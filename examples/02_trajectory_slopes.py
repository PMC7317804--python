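"""Per-group biomarker slopes from the random-intercept-and-slope model.

Fits the ML mixed model with a prospective-event-group interaction so that
subjects who later develop VTE get their own mean slope, on the raw ug/mL
scale and (for percent change) on the natural-log scale.
"""

import warnings

import jointtraj as jt
from jointtraj.longitudinal import group_slope

warnings.simplefilter("ignore")

patients, visits = jt.simulate_cohort(jt.paper_like_params(seed=2))
data = jt.build_dataset(visits, patients, time_unit="months")

fit = jt.fit_lmm(data, scale="original_ugml", group_by_event=True)
for grp in ("no_vte", "vte"):
    s, se = group_slope(fit, grp)
    print(f"slope[{grp}] = {s:+.3f} ug/mL/month (SE {se:.3f})")
diff, (lo, hi), p = jt.slope_contrast(fit)
print(f"difference  = {diff:+.3f} ug/mL/month (95% CI {lo:.2f} to {hi:.2f}, p={p:.2g})")

fit_log = jt.fit_lmm(data, scale="natural_log", group_by_event=True)
for grp, (pct, (lo, hi)) in jt.percent_change_per_month(fit_log).items():
    print(f"percent change[{grp}] = {pct:+.1f}%/month ({lo:.1f} to {hi:.1f})")

print(
    "\nA clearly positive VTE-group slope with a flat no-VTE group shows the "
    "biomarker rising in the months before thrombosis."
)
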