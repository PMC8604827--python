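"""Fit the three-compartment disposition model to simulated bolus data.

Generates a noisy 15 mg IV bolus profile from the methotrexate preset,
refits the six disposition parameters by weighted nonlinear least squares,
and reports the recovery error.
"""

import numpy as np

from iapbpk import fit_three_compartment, mtx_pk_preset, simulate_iv_bolus
from iapbpk.systemic import PARAM_NAMES

truth = mtx_pk_preset(body_weight=70.0)
times = np.geomspace(0.05, 48.0, 14)
_, conc = simulate_iv_bolus(truth, dose_mg=15.0, duration_h=48.0, times_h=times)

rng = np.random.default_rng(7)
noisy = conc * np.exp(rng.normal(0.0, 0.10, conc.size))  # ~10% lognormal noise

init = truth.copy_with(cl_renal=120.0, vc=45.0, k12=4.0, k21=0.6, k13=0.3, k31=0.02)
fit = fit_three_compartment(times, noisy, dose_mg=15.0, body_weight=70.0,
                            init=init, seed=1)

print(f"{'parameter':<10}{'true':>10}{'fitted':>10}{'error %':>9}")
for name in PARAM_NAMES:
    t, f = getattr(truth, name), getattr(fit.params, name)
    print(f"{name:<10}{t:>10.3f}{f:>10.3f}{100 * (f / t - 1):>9.1f}")
print()
print(f"converged: {fit.converged}, multi-starts: {fit.n_starts}")
print("Clearance and central volume are tightly identified from bolus data;")
print("the slow deep-compartment constants (k13, k31) carry the widest error,")
print("as expected when the terminal phase is sampled over only two days.")
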