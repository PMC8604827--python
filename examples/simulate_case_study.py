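"""Simulate 5 mg methotrexate injected into a healthy and an RA knee.

Reproduces the package's core result: the same dose produces a sharp,
early plasma peak from a healthy joint but a flattened, delayed peak from
an RA joint (large effusion diluting the dose, thickened synovium), while
total systemic exposure (AUC) barely changes.
"""

from iapbpk import (
    OBSERVED_MTX_IA,
    DoseEvent,
    SimulationSettings,
    compute_metrics,
    healthy_knee_preset,
    mtx_pk_preset,
    mtx_preset,
    ra_knee_preset,
    simulate,
)

cmpd = mtx_preset()
pk = mtx_pk_preset(body_weight=70.0)
dose = DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0, form="solution")
settings = SimulationSettings(duration=25.0)

print(f"{'':<10}{'plasma Cmax':>12}{'Tmax':>7}{'plasma AUC':>12}{'SF AUC':>10}")
print(f"{'':<10}{'(ng/mL)':>12}{'(h)':>7}{'(ng·h/mL)':>12}{'(µg·h/mL)':>10}")
for label, phys in [("healthy", healthy_knee_preset()), ("ra", ra_knee_preset())]:
    res = simulate(phys, cmpd, pk, dose, settings)
    plasma = compute_metrics(res.time, res.trace("plasma"), t_end=25.0)
    sf = compute_metrics(res.time, res.trace("synovial_fluid"), t_end=25.0)
    print(f"{label:<10}{plasma.cmax:>12.1f}{plasma.tmax:>7.2f}"
          f"{plasma.auc_0_t:>12.1f}{sf.auc_0_t:>10.1f}")

obs = OBSERVED_MTX_IA
print(f"{'observed':<10}{obs['plasma']['cmax']:>12.1f}{obs['plasma']['tmax']:>7.2f}"
      f"{obs['plasma']['auc_0_t']:>12.1f}{obs['synovial_fluid']['auc_0_t']:>10.1f}")
print()
print("The RA effusion (30 mL vs 2.21 mL) dilutes the dose and the thickened")
print("synovium slows uptake: plasma Cmax drops ~3.6-fold and Tmax moves from")
print("~0.3 h to ~1 h, while AUC(0-25) is nearly conserved — the observed RA")
print("plasma kinetics are matched only with the diseased physiology.")
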