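# Methods

## Model structure

The joint is a set of well-mixed mass compartments: an optional
undissolved depot, the synovial fluid (SF), the intima, the subintima,
and `n` cartilage sublayers (default 10), coupled to a three-compartment
systemic disposition model. State is carried as **masses**, so total mass
(compartments + cumulative elimination) is conserved structurally: every
exchange term enters the right-hand side twice with opposite signs.
Concentrations, reported on output, are `mass / volume`; unbound
concentrations are `Cu = fu_t · C` with a per-tissue fraction unbound,
and every inter-compartment gradient is evaluated on unbound
concentrations — bound drug is immobile.

Volumes derive from anatomy: `V_int = SA_syn·h_int`,
`V_subint = SA_syn·h_subint`, `V_cart,j = SA_cart·h_cart/n`. An IA
injection mixes its vehicle instantly into the SF
(`V_sf = resident + vehicle`) and the volume stays constant afterwards
(no fluid turnover is modelled).

### Exchange terms

| path | rate law |
|---|---|
| SF ↔ cartilage layer 1 | `k_syn,cart · SA_cart · (Cu_sf − Cu_cart,1)` |
| cartilage j ↔ j+1 | flux form `(D_cart·SA_cart/h_j)(Cu_j − Cu_{j+1})`; deepest layer closed (zero-flux bone side) |
| SF ↔ intima | `k_syn,int · SA_syn · (Cu_sf − Cu_int)` with `1/k_syn,int = 1/k_syn,bl + h_int/D_int` |
| intima ↔ subintima | `(D_subint/h_subint) · SA_syn · (Cu_int − Cu_subint)` |
| subintima ↔ plasma | `Q · R_bp · (Cu_subint/f_up − C_p)` |
| central ↔ peripherals | first-order `k12/k21`, `k13/k31`; elimination `CL·C_p` from central only (renal) |

The cartilage interior stencil is the standard second-difference Fick
discretisation; written in flux form it conserves mass exactly and, at 50
sublayers, tracks the analytic cosine-series solution of an insulated
slab within 1 % (tested).

### Film coefficients

Both fluid-side films use the laminar flat-plate correlation
`k = (D_bl/L) · 0.664 · Re^{1/2} · Sc^{1/3}`, with `Re = ρ v L/µ`,
`Sc = µ/(ρ D_bl)`, v = 1.5 cm/s (fluid-dynamics estimate of joint fluid
velocity), ρ = 1 g/mL, and µ the bulk SF viscosity (389.5 cP). Length
scales: `L_cart = 0.207 × cartilage thickness` (the synovial gap over the
cartilage) and `L_syn`, the characteristic height of the synovium surface
(default: the healthy fluid-film height, `V_sf/SA_syn` of the healthy
joint ≈ 80 µm).

**Which diffusivity belongs in the correlation** is the one genuinely
open modelling choice. Measured small-solute diffusion in synovial fluid
and cartilage is close to aqueous — the hyaluronan network confers bulk
viscosity without obstructing microscopic diffusion — so all *tissue*
diffusivities default to the aqueous value. The *boundary layer*,
however, is macroscopic fluid: its unstirred-film thickness is set by the
bulk hydrodynamics, and using the aqueous diffusivity there makes
absorption from the joint several-fold faster than clinically observed
IA kinetics. The default (`SimulationSettings.boundary_layer_diffusivity
= "stokes_einstein"`) therefore computes the in-film diffusivity from
Stokes–Einstein, `D = k_B T/(6π µ r)`, at the bulk SF viscosity, with the
solute radius inverted from the aqueous diffusivity at water viscosity
(0.69 cP, 37 °C) so the two routes agree exactly in water. `"water"` and
`"tissue"` switches expose the alternatives.

`L_syn` is carried as an explicit physiology parameter rather than
recomputed from the instantaneous fluid volume: it characterises the
synovium surface geometry, and an effusion does not rescale it. The RA
preset therefore keeps the healthy value — consistent with representing
RA by exactly three parameter changes — and one-at-a-time sweeps of
`sf_volume` genuinely vary one parameter. Setting `l_syn: null` in a
physiology file restores the derived `V_sf/SA_syn` default.

### Dissolution and precipitation

Suspension doses dissolve by a Nernst–Brunner film model for
monodisperse particles (diffusion-layer thickness = particle radius),
driven by the gap between solubility at SF pH and the unbound dissolved
concentration; dissolved drug above solubility precipitates first-order
with the mean precipitation time (900 s default). Solubility scales from
the reference pH by Henderson–Hasselbalch factors when ionisation
constants are supplied. Solution doses bypass the machinery by default
(`allow_precipitation=False`): a formulated solution is taken to remain
in solution. This matters for compounds shipped without pKa data — the
methotrexate preset carries its reference solubility at pH 4.2 only, and
letting it "precipitate" at pH 7.7, where the real (ionised) solubility
is orders of magnitude higher, would be an artefact of the missing
ionisation constants, not physics.

## Parameters

| parameter | default | unit | note |
|---|---|---|---|
| SF volume | 2.21 (healthy) / 30 (RA) | mL | RA effusions measured 15–60 mL |
| SF viscosity | 389.5 | cP | bulk, hydrodynamics only |
| SF pH | 7.7 | – | governs solubility scaling |
| synovium area | 277 | cm² | intima = subintima |
| cartilage area / thickness | 148 / 2.5 | cm² / mm | 10 sublayers |
| intima thickness | 18 / 162 | µm | 1–2 vs 8–10 cell layers |
| subintima thickness | 282 / 705 | µm | capillaries within ~300 µm |
| blood flow density | 0.63 | mL/min/mL synovium | converts to `Q` via synovium volume |
| fluid velocity | 1.5 | cm/s | CFD/PIV-based estimate |
| temperature | 310.15 | K | |
| gap factor | 0.207 | – | `L_cart`/cartilage thickness |
| SF density | 1.0 | g/mL | aqueous fluid, not tabulated elsewhere |

`Q` defaults to blood-flow density × total synovium volume
(intima + subintima), because the density is quoted per mL of synovium;
`q_volume_convention="subintima"` restricts it to the vascularised layer
(difference < 1 % on every case-study metric). Body weight is an explicit
input (70 kg default for the IA scenario). Disease progression
interpolates the three RA parameters linearly in the progression
fraction; a per-parameter breakpoint table can replace the linear ramp
if staged measurements are available.

## Numerics

Stiff BDF integration with `rtol = 1e-8`, `atol = 1e-12` mg and an
analytic constant Jacobian for solution doses (the system is then
linear); dense output on a 0.01 h grid over 0–25 h for metric extraction.
Halving the tolerances moves Cmax/AUC by < 0.1 %. States are clipped to
zero at output only within `max(1e4·atol, 1e-9·dose)`; larger negativity
is a hard error. Mass-balance residual is reported at every output point
and stays < 1e-11 mg on the case study (tolerance 1e-6 × dose).
Cmax/Tmax are read off the dense grid (earliest attainment breaks ties);
AUC is linear-trapezoidal.

The systemic model is solved through the eigen-decomposition of its rate
matrix (exact); an ODE route is kept solely as an independent cross-check
(agreement < 1e-8 relative, tested). Parameter fitting minimises
prediction-weighted residuals `(y − ŷ)/ŷ` in log-parameter space
(trust-region reflective, 1000-fold bounds) from a deterministic set of
multi-starts jittered around the initial guess; parameters finishing on
a bound raise an identifiability warning.

## Synthetic-data scope

The parameter-recovery study generates its own data: analytic bolus
profiles at 12 log-spaced sampling times over 48 h, multiplied by 10 %
lognormal noise (mean-one), refit from a jittered start — 100 replicates,
seeded. This emulates the sampling density and assay noise of a typical
bolus PK study but not its real-world complications (assay LLOQ
censoring, inter-individual variability, dosing-history errors), so
passing recovery (median |bias| of CL and Vc well under 5 %) demonstrates
estimator correctness, not robustness to those artefacts. Likewise the
IA simulations are deterministic model evaluations; agreement with
published exposure metrics validates the mechanism set, not
inter-patient variability.

## Known limitations

* Regional heterogeneity of synovium thickness is not represented; the
  joint is a single homogeneous cavity.
* Late-RA cartilage/bone destruction and disease-driven changes in
  protein binding are not modelled.
* No fluid turnover: SF volume is constant after injection.
* The deep cartilage boundary is closed; any transport across the
  osteochondral junction is neglected.
* The commercial solver this model parallels is closed: residual
  structural differences remain, visible as a ~25 % overprediction of the
  healthy-joint plasma peak and a ~13 % overprediction of the RA
  synovial-fluid AUC against the published simulation values, with the
  other case-study metrics well inside 10 %.
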