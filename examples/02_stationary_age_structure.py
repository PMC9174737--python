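"""Stationary age structure and ageing side-effects of a delay policy.

Solves the full stationary state (growth rate, childless density h0,
mother density h(a, tau), total density h_tot) for a mild and a harsh
refractory period and summarizes how the age distribution shifts.
"""

import numpy as np

import birthdelay as bd

preset = bd.china_like_preset()
beta0 = bd.reconstruct_beta0(preset.beta_eff, preset.natural_delta)

for delta in (2.0, 8.0):
    st = bd.stationary_state(beta0, bd.PolicyConfig(delta=delta), preset.mu_f)
    peak_age = st.grid.nodes[np.argmax(st.h_tot.values)]
    senior = bd.senior_fraction(st.h_tot)
    childless = st.grid.trapz(st.h0.values)
    print(f"delta = {delta:g} yr:")
    print(f"  lambda            = {st.lam:+.6f} /yr")
    print(f"  h_tot peak age    = {peak_age:.1f} yr")
    print(f"  seniors (65+)     = {100 * senior:.1f} %")
    print(f"  childless share   = {100 * childless:.1f} % of females")

# A growing population (delta = 2) has a monotonically decreasing h_tot with
# its peak at age 0; once lambda < 0 the peak moves to an interior age and
# the senior share climbs — the ageing cost of birth-spacing policies.
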