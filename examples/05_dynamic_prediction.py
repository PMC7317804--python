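"""Dynamic individualized VTE-risk prediction from a fitted joint model.

Two synthetic patients with identical baselines but different D-dimer
histories: one stable, one rising.  Predictions condition on each history
and on being event-free at the last visit (the landmark).
"""

import warnings

import numpy as np
import pandas as pd

import jointtraj as jt
from jointtraj.jointmodel import JointModelSpec

warnings.simplefilter("ignore")

patients, visits = jt.simulate_cohort(jt.paper_like_params(seed=5).with_(n_subjects=250))
data = jt.build_dataset(visits, patients, time_unit="months")
fit = jt.fit_joint_model(data, JointModelSpec(scale="log2"))

landmark = 3.0  # months since baseline
horizons = landmark + np.array([0.0, 2.0, 4.0, 6.0])
stable = pd.DataFrame({"time": [0, 1, 2, 3], "ddimer_ugml": [1.6, 1.5, 1.7, 1.6]})
rising = pd.DataFrame({"time": [0, 1, 2, 3], "ddimer_ugml": [0.8, 1.2, 1.9, 3.0]})

for label, hist in [("stable", stable), ("rising", rising)]:
    pred = jt.predict_risk(fit, hist, {}, landmark=landmark, horizons=horizons,
                           n_mc_draws=500, seed=11, patient_id=label)
    r, lo, hi = pred.risk[-1], pred.ci_lower[-1], pred.ci_upper[-1]
    print(f"{label:7s} 6-month VTE risk: {100*r:5.1f}%  (95% band {100*lo:.1f}-{100*hi:.1f}%)")

print(
    "\nThe rising trajectory should carry a several-fold higher conditional "
    "risk than the stable one — the dynamic updating a single baseline "
    "measurement cannot provide."
)
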