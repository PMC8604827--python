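"""Intra-articular disposition model: the coupled joint + systemic ODE system.

State layout (all amounts in mg):

    [undissolved, m_sf, m_int, m_subint, m_cart_1 .. m_cart_n,
     a_central, a_periph2, a_periph3, eliminated]

Mechanisms wired into the right-hand side:

* dissolution / precipitation of a particulate depot in the synovial fluid
  (Nernst-Brunner film dissolution; first-order precipitation above
  solubility) — engaged for suspension doses;
* convective-film exchange between synovial fluid and the first cartilage
  sublayer, and Fickian diffusion through the cartilage sublayers with a
  zero-flux (bone-side) deep boundary;
* series boundary-layer + intima film exchange between synovial fluid and
  intima, then a subintima diffusion film;
* perfusion-limited uptake from the vascularised subintima into the central
  compartment, driven by the unbound-concentration partition
  Q * Rbp * (Cu_subint / fup - Cp);
* three-compartment systemic disposition with renal elimination.

Only unbound drug moves between tissues: every gradient is evaluated on
``fu_tissue * mass / volume``.  The state is carried as masses so that
conservation is structural — every flux appears once with each sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .compound import CompoundProperties, diffusivity_stokes_einstein, solubility_at_ph
from .physiology import JointPhysiology, synovium_volume
from .systemic import SystemicPKParams, rate_matrix
from .transport import TransportCoefficients, compute_transport

__all__ = [
    "DoseEvent",
    "SimulationSettings",
    "SimulationResult",
    "build_volumes",
    "dissolution_precipitation_rate",
    "sf_cart_flux",
    "cartilage_diffusion_rhs",
    "synovium_fluxes",
    "systemic_uptake_rate",
    "simulate",
]

S_PER_H = 3600.0


@dataclass
class DoseEvent:
    """A single administration.

    route : "IA" (into the synovial fluid) or "IV_bolus" (into plasma)
    amount : dose, mg
    vehicle_volume : injected vehicle volume added to the SF, mL (IA only)
    time : administration time, h (traces are zero before it)
    form : "solution" (fully dissolved at t0) or "suspension"
           (fully undissolved at t0, dissolving in the SF)
    """

    route: str
    amount: float
    vehicle_volume: float = 0.0
    time: float = 0.0
    form: str = "solution"

    def __post_init__(self) -> None:
        if self.route not in ("IA", "IV_bolus"):
            raise ValueError(f"route must be 'IA' or 'IV_bolus', got {self.route!r}")
        if self.form not in ("solution", "suspension"):
            raise ValueError(f"form must be 'solution' or 'suspension', got {self.form!r}")
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.vehicle_volume < 0 or self.time < 0:
            raise ValueError("vehicle_volume and time must be non-negative")


@dataclass
class SimulationSettings:
    """Numerical and reporting controls for one run.

    duration : simulated span after the dose, h
    output_step : dense reporting grid spacing, h
    rtol/atol : integrator tolerances (atol in mg)
    q_volume_convention : "total" uses the whole synovium volume
        (intima + subintima) to convert the perfusion density into a blood
        flow; "subintima" restricts it to the vascularised layer only
    first_obs_time : optional sampling time (h) at which an additional SF
        "concentration at first measurement" is reported
    allow_precipitation : let a supersaturated solution precipitate back to
        particulate material.  Off by default for solution doses: a drug
        formulated as a solution is taken to stay in solution, since its
        effective solubility at the vehicle/tissue pH is what made the
        formulation possible in the first place (ionisation data, when
        supplied, make this explicit through the pH-solubility profile).
    boundary_layer_diffusivity : which diffusion coefficient enters the
        flat-plate correlations for the fluid films at the cartilage and
        synovium surfaces.  "stokes_einstein" (default) derives it from the
        bulk synovial-fluid viscosity — the unstirred boundary layer is
        macroscopic fluid, where the hyaluronan network's bulk viscosity
        applies; "water" uses the aqueous diffusivity (free microscopic
        diffusion extended into the film); "tissue" defers to the
        compound's synovial-fluid diffusivity mode.
    """

    duration: float = 25.0
    output_step: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-12
    q_volume_convention: str = "total"
    first_obs_time: float | None = None
    allow_precipitation: bool = False
    boundary_layer_diffusivity: str = "stokes_einstein"

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.output_step <= 0:
            raise ValueError("duration and output_step must be positive")
        if self.q_volume_convention not in ("total", "subintima"):
            raise ValueError("q_volume_convention must be 'total' or 'subintima'")
        if self.boundary_layer_diffusivity not in ("stokes_einstein", "water", "tissue"):
            raise ValueError(
                "boundary_layer_diffusivity must be 'stokes_einstein', 'water' or 'tissue'"
            )


@dataclass
class SimulationResult:
    """Dense concentration-time output of one simulation.

    ``traces`` maps compartment names to concentration arrays in their
    native reporting units: plasma in ng/mL, joint compartments in µg/mL,
    plus the undissolved depot mass in mg.  ``masses`` carries the raw
    per-compartment amounts (mg).  ``mass_balance_residual`` is
    dose - (sum of all amounts + eliminated) at every output time.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    masses: dict[str, np.ndarray]
    mass_balance_residual: np.ndarray
    volumes: dict[str, float]
    transport: TransportCoefficients | None
    dose: DoseEvent
    sf_cmax_at_first_obs: float | None = None

    def trace(self, name: str) -> np.ndarray:
        return self.traces[name]

    def to_frame(self):
        """Tidy long-format DataFrame: time, compartment, concentration, units."""
        import pandas as pd

        units = {name: ("ng/mL" if name == "plasma" else "mg" if name == "undissolved" else "ug/mL")
                 for name in self.traces}
        frames = [
            pd.DataFrame(
                {
                    "time_h": self.time,
                    "compartment": name,
                    "concentration": values,
                    "units": units[name],
                }
            )
            for name, values in self.traces.items()
        ]
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------- #
# Building blocks (exposed for testing and inspection)
# --------------------------------------------------------------------- #

def build_volumes(phys: JointPhysiology, dose: DoseEvent | None = None) -> dict[str, float]:
    """Compartment volumes in mL; the injected vehicle mixes instantly into the SF."""
    vehicle = dose.vehicle_volume if (dose is not None and dose.route == "IA") else 0.0
    h_j = phys.cartilage_sublayer_thickness_cm
    return {
        "synovial_fluid": phys.sf_volume + vehicle,
        "intima": phys.synovium_area * phys.intima_thickness * 1e-4,
        "subintima": phys.synovium_area * phys.subintima_thickness * 1e-4,
        "cartilage_sublayer": phys.cartilage_area * h_j,
        "cartilage_total": phys.cartilage_area * phys.cartilage_thickness * 0.1,
    }


def dissolution_precipitation_rate(
    cmpd: CompoundProperties,
    undissolved_mg: float,
    dissolved_mg: float,
    sf_volume_ml: float,
    sf_ph: float,
    d_syn_cm2_s: float | None = None,
    fu_sf: float | None = None,
) -> float:
    """Net dissolution rate in the synovial fluid, mg/h (negative = precipitation).

    Dissolution follows a Nernst-Brunner film model for monodisperse
    particles with a diffusion-layer thickness equal to the particle
    radius; the driving force is the gap between the solubility at SF pH
    and the unbound dissolved concentration.  Above solubility the excess
    dissolved drug precipitates first-order with the mean precipitation
    time.
    """
    d_syn = cmpd.d_aqueous if d_syn_cm2_s is None else d_syn_cm2_s
    fu = cmpd.fu_tissue["synovial_fluid"] if fu_sf is None else fu_sf
    sol = solubility_at_ph(cmpd, sf_ph)
    conc_total = dissolved_mg / sf_volume_ml
    conc_unbound = fu * conc_total

    if conc_total > sol:
        tau_h = cmpd.mean_precipitation_time / S_PER_H
        return -(conc_total - sol) * sf_volume_ml / tau_h

    if undissolved_mg > 0.0 and conc_unbound < sol:
        r_cm = cmpd.particle_radius * 1e-4
        rho_mg_ml = cmpd.particle_density * 1e3
        d_cm2_h = d_syn * S_PER_H
        return 3.0 * d_cm2_h * undissolved_mg / (rho_mg_ml * r_cm**2) * (sol - conc_unbound)

    return 0.0


def sf_cart_flux(cu_syn: float, cu_cart1: float, k_syn_cart_cm_s: float,
                 cartilage_area_cm2: float) -> float:
    """SF -> first cartilage sublayer mass flow, mg/h (unbound-gradient driven)."""
    return k_syn_cart_cm_s * S_PER_H * cartilage_area_cm2 * (cu_syn - cu_cart1)


def cartilage_diffusion_rhs(
    masses_mg: np.ndarray,
    sublayer_volume_ml: float,
    sublayer_thickness_cm: float,
    area_cm2: float,
    d_cart_cm2_s: float,
    fu_cart: float,
    upstream_flux_mg_h: float = 0.0,
) -> np.ndarray:
    """Mass rates (mg/h) for the cartilage sublayers.

    Interior sublayers follow the discrete Fick stencil on unbound
    concentrations; sublayer 1 receives ``upstream_flux_mg_h`` from the SF
    film, and the deepest sublayer has a zero-flux (bone-side) boundary.
    Written in flux form between adjacent layers, so the stencil conserves
    mass exactly.
    """
    masses_mg = np.asarray(masses_mg, dtype=float)
    n = masses_mg.size
    cu = fu_cart * masses_mg / sublayer_volume_ml
    g = d_cart_cm2_s * S_PER_H * area_cm2 / sublayer_thickness_cm  # mL/h
    rates = np.zeros(n)
    rates[0] += upstream_flux_mg_h
    inter = g * (cu[:-1] - cu[1:])  # flux layer j -> j+1, mg/h
    rates[:-1] -= inter
    rates[1:] += inter
    return rates


def synovium_fluxes(
    cu_syn: float,
    cu_int: float,
    cu_subint: float,
    k_syn_int_cm_s: float,
    d_subint_cm2_s: float,
    h_subint_cm: float,
    area_cm2: float,
) -> tuple[float, float]:
    """(SF -> intima, intima -> subintima) mass flows, mg/h; both bidirectional."""
    j_sf_int = k_syn_int_cm_s * S_PER_H * area_cm2 * (cu_syn - cu_int)
    j_int_sub = d_subint_cm2_s * S_PER_H / h_subint_cm * area_cm2 * (cu_int - cu_subint)
    return j_sf_int, j_int_sub


def synovial_blood_flow(phys: JointPhysiology, convention: str = "total") -> float:
    """Blood flow through the synovium, mL/h, from the perfusion density."""
    if convention == "total":
        vol = synovium_volume(phys)
    else:
        vol = phys.synovium_area * phys.subintima_thickness * 1e-4
    return phys.blood_flow_density * vol * 60.0


def systemic_uptake_rate(
    cu_subint: float,
    c_plasma: float,
    q_ml_h: float,
    rbp: float,
    fup: float,
) -> float:
    """Subintima -> central compartment mass flow, mg/h.

    Perfusion-limited exchange with instant partitioning between the
    subintimal unbound concentration and plasma:
    ``Q * Rbp * (Cu_subint / fup - Cp)``; positive moves drug into plasma.
    """
    return q_ml_h * rbp * (cu_subint / fup - c_plasma)


# --------------------------------------------------------------------- #
# Assembly and integration
# --------------------------------------------------------------------- #

def _assemble(phys: JointPhysiology, cmpd: CompoundProperties,
              pk: SystemicPKParams, dose: DoseEvent, settings: SimulationSettings):
    """Pre-compute volumes, coefficients and the RHS/Jacobian closures."""
    vols = build_volumes(phys, dose)
    n = phys.n_cartilage_sublayers
    h_j = phys.cartilage_sublayer_thickness_cm
    v_sf = vols["synovial_fluid"]
    v_int = vols["intima"]
    v_sub = vols["subintima"]
    v_cart = vols["cartilage_sublayer"]

    d_syn = cmpd.tissue_diffusivity("synovial_fluid", phys.sf_viscosity, phys.temperature)
    d_int = cmpd.tissue_diffusivity("intima", temperature_k=phys.temperature)
    d_sub = cmpd.tissue_diffusivity("subintima", temperature_k=phys.temperature)
    d_cart = cmpd.tissue_diffusivity("cartilage", temperature_k=phys.temperature)

    if settings.boundary_layer_diffusivity == "stokes_einstein":
        d_bl = diffusivity_stokes_einstein(
            cmpd.radius_nm(phys.temperature), phys.sf_viscosity, phys.temperature)
    elif settings.boundary_layer_diffusivity == "water":
        d_bl = cmpd.d_aqueous
    else:
        d_bl = d_syn

    transport = compute_transport(phys, d_bl, d_int)

    fu_sf = cmpd.fu_tissue["synovial_fluid"]
    fu_int = cmpd.fu_tissue["intima"]
    fu_sub = cmpd.fu_tissue["subintima"]
    fu_cart = cmpd.fu_tissue["cartilage"]

    q = synovial_blood_flow(phys, settings.q_volume_convention)
    a_sys = rate_matrix(pk)
    vc = pk.vc_total

    # conductances, mL/h (applied to unbound concentrations)
    g_cart_film = transport.k_syn_cart * S_PER_H * phys.cartilage_area
    g_int = transport.k_syn_int * S_PER_H * phys.synovium_area
    g_sub = d_sub * S_PER_H / (phys.subintima_thickness * 1e-4) * phys.synovium_area
    g_cart = d_cart * S_PER_H * phys.cartilage_area / h_j
    g_up = q * cmpd.rbp  # multiplies (Cu_sub/fup - Cp)

    n_state = n + 8
    i_und, i_sf, i_int, i_sub = 0, 1, 2, 3
    i_cart = slice(4, 4 + n)
    i_c, i_p2, i_p3, i_el = 4 + n, 5 + n, 6 + n, 7 + n

    suspension = dose.form == "suspension" and dose.route == "IA"
    allow_prec = settings.allow_precipitation or suspension

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros(n_state)
        cu_sf = fu_sf * y[i_sf] / v_sf
        cu_int_ = fu_int * y[i_int] / v_int
        cu_sub_ = fu_sub * y[i_sub] / v_sub
        cu_cart = fu_cart * y[i_cart] / v_cart
        cp = y[i_c] / vc

        if suspension or (allow_prec and y[i_und] > 0.0):
            diss = dissolution_precipitation_rate(
                cmpd, y[i_und], y[i_sf], v_sf, phys.sf_ph, d_syn, fu_sf)
        elif allow_prec:
            diss = min(0.0, dissolution_precipitation_rate(
                cmpd, 0.0, y[i_sf], v_sf, phys.sf_ph, d_syn, fu_sf))
        else:
            diss = 0.0

        j_cart = g_cart_film * (cu_sf - cu_cart[0])
        j_int = g_int * (cu_sf - cu_int_)
        j_sub = g_sub * (cu_int_ - cu_sub_)
        uptake = g_up * (cu_sub_ / cmpd.fup - cp)

        dy[i_und] = -diss
        dy[i_sf] = diss - j_cart - j_int
        dy[i_int] = j_int - j_sub
        dy[i_sub] = j_sub - uptake

        inter = g_cart * (cu_cart[:-1] - cu_cart[1:])
        cart_rates = np.zeros(n)
        cart_rates[0] += j_cart
        if n > 1:
            cart_rates[:-1] -= inter
            cart_rates[1:] += inter
        dy[i_cart] = cart_rates

        sys_amounts = y[[i_c, i_p2, i_p3]]
        sys_rates = a_sys @ sys_amounts
        dy[i_c] = sys_rates[0] + uptake
        dy[i_p2] = sys_rates[1]
        dy[i_p3] = sys_rates[2]
        dy[i_el] = pk.k10 * y[i_c]
        return dy

    # constant Jacobian of the linear part (exact for solution doses)
    jac = np.zeros((n_state, n_state))
    jac[i_sf, i_sf] += -(g_cart_film + g_int) * fu_sf / v_sf
    jac[i_sf, i_cart.start] += g_cart_film * fu_cart / v_cart
    jac[i_sf, i_int] += g_int * fu_int / v_int
    jac[i_int, i_sf] += g_int * fu_sf / v_sf
    jac[i_int, i_int] += -(g_int + g_sub) * fu_int / v_int
    jac[i_int, i_sub] += g_sub * fu_sub / v_sub
    jac[i_sub, i_int] += g_sub * fu_int / v_int
    jac[i_sub, i_sub] += -g_sub * fu_sub / v_sub - g_up * fu_sub / (v_sub * cmpd.fup)
    jac[i_sub, i_c] += g_up / vc
    # cartilage block
    k1 = i_cart.start
    jac[k1, i_sf] += g_cart_film * fu_sf / v_sf
    jac[k1, k1] += -g_cart_film * fu_cart / v_cart
    for j in range(n - 1):
        a, b = k1 + j, k1 + j + 1
        jac[a, a] += -g_cart * fu_cart / v_cart
        jac[a, b] += g_cart * fu_cart / v_cart
        jac[b, a] += g_cart * fu_cart / v_cart
        jac[b, b] += -g_cart * fu_cart / v_cart
    # systemic block
    jac[np.ix_([i_c, i_p2, i_p3], [i_c, i_p2, i_p3])] += a_sys
    jac[i_c, i_sub] += g_up * fu_sub / (v_sub * cmpd.fup)
    jac[i_c, i_c] += 0.0
    jac[i_el, i_c] += pk.k10

    use_const_jac = not (suspension or allow_prec)

    return vols, transport, rhs, (jac if use_const_jac else None), (n, i_cart)


def simulate(
    phys: JointPhysiology,
    cmpd: CompoundProperties,
    pk: SystemicPKParams,
    dose: DoseEvent,
    settings: SimulationSettings | None = None,
) -> SimulationResult:
    """Integrate the full joint + systemic system for one dose event.

    Returns dense traces on a uniform grid covering ``[0, dose.time +
    settings.duration]``; concentrations before the dose are zero.  Raises
    if the integrator fails or if any state goes negative beyond a small
    numerical tolerance.
    """
    settings = settings or SimulationSettings()
    vols, transport, rhs, jac, (n, i_cart) = _assemble(phys, cmpd, pk, dose, settings)

    n_state = n + 8
    y0 = np.zeros(n_state)
    if dose.route == "IA":
        if dose.form == "suspension":
            y0[0] = dose.amount
        else:
            y0[1] = dose.amount
    else:
        y0[4 + n] = dose.amount

    t_grid = np.arange(0.0, settings.duration + settings.output_step / 2, settings.output_step)
    sol = solve_ivp(
        rhs,
        (0.0, settings.duration),
        y0,
        method="BDF",
        t_eval=t_grid,
        jac=(lambda t, y: jac) if jac is not None else None,
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed ({sol.message}); check parameter consistency "
            f"(volumes {vols}, dose {dose})"
        )

    y = sol.y  # n_state x n_t
    neg_tol = max(1e4 * settings.atol, 1e-9 * dose.amount)
    if y.min() < -neg_tol:
        idx = np.unravel_index(np.argmin(y), y.shape)
        raise RuntimeError(
            f"negative state beyond tolerance: state {idx[0]} = {y.min():.3e} mg "
            f"at t = {sol.t[idx[1]]:.3f} h"
        )
    y = np.clip(y, 0.0, None)

    total = y.sum(axis=0)
    residual = dose.amount - total

    if dose.time > 0:
        # shift the grid: zeros before the administration time
        pre = np.arange(0.0, dose.time, settings.output_step)
        t_out = np.concatenate([pre, dose.time + sol.t])
        pad = np.zeros((n_state, pre.size))
        y = np.concatenate([pad, y], axis=1)
        residual = np.concatenate([np.zeros(pre.size), residual])
    else:
        t_out = sol.t

    v_sf, v_int, v_sub = vols["synovial_fluid"], vols["intima"], vols["subintima"]
    v_cart_tot = vols["cartilage_total"]
    cart_mass = y[4:4 + n].sum(axis=0)

    traces = {
        "plasma": y[4 + n] / pk.vc_total * 1e6,            # ng/mL
        "synovial_fluid": y[1] / v_sf * 1e3,               # µg/mL
        "intima": y[2] / v_int * 1e3,
        "subintima": y[3] / v_sub * 1e3,
        "cartilage_mean": cart_mass / v_cart_tot * 1e3,
        "undissolved": y[0],                               # mg
    }
    masses = {
        "undissolved": y[0],
        "synovial_fluid": y[1],
        "intima": y[2],
        "subintima": y[3],
        "cartilage": cart_mass,
        "central": y[4 + n],
        "periph2": y[5 + n],
        "periph3": y[6 + n],
        "eliminated": y[7 + n],
    }

    sf_first = None
    if settings.first_obs_time is not None:
        sf_first = float(np.interp(settings.first_obs_time, t_out, traces["synovial_fluid"]))

    return SimulationResult(
        time=t_out,
        traces=traces,
        masses=masses,
        mass_balance_residual=residual,
        volumes=vols,
        transport=transport,
        dose=dose,
        sf_cmax_at_first_obs=sf_first,
    )
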