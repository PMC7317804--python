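"""Cumulative VTE incidence with death as a competing risk.

Compares the Aalen-Johansen cumulative incidence function with the naive
1-Kaplan-Meier estimate (deaths censored), which overstates the incidence
whenever competing deaths occur.
"""

import jointtraj as jt

# constant-hazard benchmark where the true CIF has a closed form
coh = jt.simulate_competing_constant_hazards(
    n=100_000, lambda_vte=5.617e-4, lambda_death=6.45e-4,
    admin_censor_days=250.0, seed=3,
)
cif_vte, cif_death = jt.aalen_johansen(coh)
km = jt.kaplan_meier(coh)

print(f"Aalen-Johansen CIF_VTE(250d) = {100 * cif_vte.at(250):.1f}%")
print(f"1 - Kaplan-Meier (250d)      = {100 * km.at(250):.1f}%")
print(f"CIF_death(250d)              = {100 * cif_death.at(250):.1f}%")
print(
    "\nThe ~1 percentage-point excess of 1-KM over the CIF is the upward "
    "bias of censoring competing deaths; the CIF is the probability a "
    "patient actually experiences VTE by day 250."
)
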