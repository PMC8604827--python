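"""Compound (API) parameter sets and diffusivity/solubility estimation.

Three routes are supported for tissue diffusion coefficients:

``water``
    use the aqueous diffusion coefficient unchanged.  Measurements of
    small-solute diffusion in cartilage and synovial fluid support this:
    the hyaluronan network gives the fluid its bulk viscosity but barely
    hinders diffusion of small molecules.
``stokes_einstein``
    D = k_B T / (6 pi eta r), i.e. diffusion slowed by the bulk viscosity.
``logd_qspr``
    an empirical lipophilicity correlation developed for soft-tissue
    diffusivity, driven by logD at pH 7.4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "CompoundProperties",
    "mtx_preset",
    "diffusivity_stokes_einstein",
    "diffusivity_logd_qspr",
    "solubility_at_ph",
    "molecular_radius_from_daq",
]

BOLTZMANN_J_PER_K = 1.380649e-23
WATER_VISCOSITY_37C_CP = 0.69

JOINT_TISSUES = ("synovial_fluid", "intima", "subintima", "cartilage")
DIFFUSIVITY_MODES = ("water", "stokes_einstein", "logd_qspr")


def diffusivity_stokes_einstein(radius_nm: float, viscosity_cp: float, temperature_k: float) -> float:
    """Stokes-Einstein diffusion coefficient, cm^2/s.

    Parameters are the solute hydrodynamic radius (nm), the solvent dynamic
    viscosity (cP) and the absolute temperature (K).
    """
    if radius_nm <= 0 or viscosity_cp <= 0 or temperature_k <= 0:
        raise ValueError("radius, viscosity and temperature must be strictly positive")
    eta_pa_s = viscosity_cp * 1e-3
    r_m = radius_nm * 1e-9
    d_m2_s = BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * eta_pa_s * r_m)
    return d_m2_s * 1e4  # m^2/s -> cm^2/s


def molecular_radius_from_daq(d_aqueous: float, temperature_k: float = 310.15) -> float:
    """Solute radius (nm) consistent with an aqueous diffusivity at 37 °C.

    Inverts the Stokes-Einstein relation at the viscosity of water so that
    the ``water`` and ``stokes_einstein`` modes agree for water by
    construction.
    """
    if d_aqueous <= 0:
        raise ValueError("d_aqueous must be positive")
    eta_pa_s = WATER_VISCOSITY_37C_CP * 1e-3
    r_m = BOLTZMANN_J_PER_K * temperature_k / (6.0 * math.pi * eta_pa_s * d_aqueous * 1e-4)
    return r_m * 1e9


def diffusivity_logd_qspr(log_d_74: float) -> float:
    """Tissue diffusivity (cm^2/s) from logD(7.4) by an empirical QSPR.

    Quadratic in logD up to logD = 3, constant above (the correlation was
    calibrated on soft epithelial tissue and saturates for lipophilic
    solutes).
    """
    if log_d_74 > 3.0:
        return 10.0 ** (-5.9514)
    return 10.0 ** (-0.0803 * log_d_74**2 + 0.5006 * log_d_74 - 6.7316)


@dataclass
class CompoundProperties:
    """Physicochemical, binding and particle parameters of the API.

    ``fu_tissue`` maps each joint tissue to its fraction unbound; only the
    unbound concentration diffuses between compartments.  ``diffusivity_mode``
    selects, per tissue, how the local diffusion coefficient is estimated.
    """

    name: str
    log_p: float
    d_aqueous: float                      # cm^2/s
    reference_solubility: float           # mg/mL
    reference_solubility_ph: float
    fup: float                            # fraction unbound in plasma
    rbp: float                            # blood/plasma ratio
    fu_tissue: dict[str, float]
    log_d_74: float | None = None
    pka_list: list[tuple[float, str]] = field(default_factory=list)
    molecular_radius: float | None = None  # nm; derived from d_aqueous if None
    particle_radius: float = 25.0          # µm
    precipitate_radius: float = 1.0        # µm
    particle_density: float = 1.2          # g/mL
    mean_precipitation_time: float = 900.0  # s
    diffusivity_mode: dict[str, str] = field(
        default_factory=lambda: {t: "water" for t in JOINT_TISSUES}
    )

    def __post_init__(self) -> None:
        if not 0 < self.fup <= 1:
            raise ValueError("fup must lie in (0, 1]")
        if self.rbp <= 0 or self.d_aqueous <= 0:
            raise ValueError("rbp and d_aqueous must be positive")
        for t in JOINT_TISSUES:
            if t not in self.fu_tissue:
                raise ValueError(f"fu_tissue missing entry for {t!r}")
            if not 0 < self.fu_tissue[t] <= 1:
                raise ValueError(f"fu_tissue[{t!r}] must lie in (0, 1]")
        for f in ("particle_radius", "precipitate_radius", "particle_density", "mean_precipitation_time"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")
        for t, mode in self.diffusivity_mode.items():
            if mode not in DIFFUSIVITY_MODES:
                raise ValueError(f"unknown diffusivity mode {mode!r} for tissue {t!r}")
        for pka, kind in self.pka_list:
            if kind not in ("acid", "base"):
                raise ValueError(f"pKa type must be 'acid' or 'base', got {kind!r}")

    def radius_nm(self, temperature_k: float = 310.15) -> float:
        if self.molecular_radius is not None:
            return self.molecular_radius
        return molecular_radius_from_daq(self.d_aqueous, temperature_k)

    def tissue_diffusivity(self, tissue: str, viscosity_cp: float | None = None,
                           temperature_k: float = 310.15) -> float:
        """Diffusion coefficient in a joint tissue, cm^2/s.

        ``viscosity_cp`` is only consulted in ``stokes_einstein`` mode; it is
        the viscosity of the medium the solute actually diffuses through.
        """
        mode = self.diffusivity_mode.get(tissue, "water")
        if mode == "water":
            return self.d_aqueous
        if mode == "stokes_einstein":
            eta = WATER_VISCOSITY_37C_CP if viscosity_cp is None else viscosity_cp
            return diffusivity_stokes_einstein(self.radius_nm(temperature_k), eta, temperature_k)
        if self.log_d_74 is None:
            raise ValueError("logd_qspr diffusivity mode requires log_d_74")
        return diffusivity_logd_qspr(self.log_d_74)

    def to_dict(self) -> dict:
        return asdict(self)

    def copy_with(self, **changes) -> "CompoundProperties":
        return replace(self, **changes)


def solubility_at_ph(cmpd: CompoundProperties, ph: float) -> float:
    """Aqueous solubility at a target pH, mg/mL.

    With no ionisation data the reference solubility is used unchanged.
    Otherwise Henderson-Hasselbalch scaling is applied: the total solubility
    is the intrinsic solubility times an ionisation factor, so

        S(pH) = S_ref * f(pH) / f(pH_ref)

    with cumulative factors for multiprotic acids/bases.
    """
    if not cmpd.pka_list:
        return cmpd.reference_solubility

    def ionisation_factor(target_ph: float) -> float:
        acids = sorted(p for p, kind in cmpd.pka_list if kind == "acid")
        bases = sorted((p for p, kind in cmpd.pka_list if kind == "base"), reverse=True)
        factor = 1.0
        exponent = 0.0
        for pka in acids:
            exponent += target_ph - pka
            factor += 10.0 ** exponent
        exponent = 0.0
        for pka in bases:
            exponent += pka - target_ph
            factor += 10.0 ** exponent
        return factor

    return cmpd.reference_solubility * ionisation_factor(ph) / ionisation_factor(cmpd.reference_solubility_ph)


def mtx_preset() -> CompoundProperties:
    """Methotrexate parameter set for the intra-articular case study.

    Joint-tissue free fractions are assumed equal to the plasma free
    fraction (synovial fluid albumin is close to plasma levels) and all
    tissue diffusivities are taken equal to the aqueous value.  No pKa data
    are carried, so pH-dependent solubility scaling stays inactive; the
    case-study dose is a solution and never engages dissolution anyway.
    """
    return CompoundProperties(
        name="methotrexate",
        log_p=-1.85,
        d_aqueous=0.62e-5,          # cm^2/s
        reference_solubility=0.16,  # mg/mL
        reference_solubility_ph=4.2,
        fup=0.66,
        rbp=0.79,
        fu_tissue={t: 0.66 for t in JOINT_TISSUES},
        particle_radius=25.0,
        precipitate_radius=1.0,
        particle_density=1.2,
        mean_precipitation_time=900.0,
        diffusivity_mode={t: "water" for t in JOINT_TISSUES},
    )
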