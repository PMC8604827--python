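"""Convective mass-transfer coefficients at the synovial-fluid interfaces.

The fluid film separating the synovial fluid from cartilage and from the
synovial membrane is treated with the laminar flat-plate correlation

    Sh = 0.664 Re^(1/2) Sc^(1/3),    k = Sh * D / L

evaluated at two length scales: the synovial gap width over the cartilage
(L_cart) and the characteristic synovium height (L_syn).  The bulk synovial
fluid viscosity enters the hydrodynamics (Re, Sc) even when the solute
diffusivity is set to its aqueous value: the hyaluronan network controls
the macroscopic flow but not microscopic diffusion, so the two are
deliberately decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .physiology import JointPhysiology

__all__ = [
    "TransportCoefficients",
    "reynolds_schmidt",
    "flat_plate_coefficient",
    "k_syn_cart",
    "k_syn_bl",
    "k_syn_int",
    "compute_transport",
]

CP_TO_G_CM_S = 0.01  # 1 cP = 0.01 g/(cm s)


@dataclass(frozen=True)
class TransportCoefficients:
    """Dimensionless groups and film coefficients of one joint state.

    All mass-transfer coefficients are in cm/s; ``l_cart`` in cm.
    """

    reynolds: float
    schmidt: float
    k_syn_cart: float
    k_syn_bl: float
    k_syn_int: float
    l_cart: float

    def to_dict(self) -> dict:
        return {
            "reynolds": self.reynolds,
            "schmidt": self.schmidt,
            "k_syn_cart_cm_s": self.k_syn_cart,
            "k_syn_bl_cm_s": self.k_syn_bl,
            "k_syn_int_cm_s": self.k_syn_int,
            "l_cart_cm": self.l_cart,
        }


def reynolds_schmidt(phys: JointPhysiology, d_syn: float, length: float) -> tuple[float, float]:
    """Reynolds and Schmidt numbers for the synovial fluid film.

    ``d_syn`` is the solute diffusivity in the fluid (cm^2/s) and ``length``
    the characteristic length (cm).  Viscosity, density and velocity come
    from the physiology.
    """
    if d_syn <= 0 or length <= 0:
        raise ValueError("d_syn and length must be strictly positive")
    mu = phys.sf_viscosity * CP_TO_G_CM_S      # g/(cm s)
    rho = phys.sf_density                      # g/mL == g/cm^3
    v = phys.sf_velocity                       # cm/s
    reynolds = rho * v * length / mu
    schmidt = mu / (rho * d_syn)
    return reynolds, schmidt


def flat_plate_coefficient(phys: JointPhysiology, d_syn: float, length: float) -> float:
    """Laminar flat-plate film coefficient k = 0.664 (D/L) Re^1/2 Sc^1/3, cm/s."""
    reynolds, schmidt = reynolds_schmidt(phys, d_syn, length)
    return d_syn / length * 0.664 * reynolds**0.5 * schmidt ** (1.0 / 3.0)


def k_syn_cart(phys: JointPhysiology, d_syn: float) -> float:
    """SF <-> cartilage film coefficient at the synovial-gap length scale, cm/s."""
    return flat_plate_coefficient(phys, d_syn, phys.l_cart_cm)


def k_syn_bl(phys: JointPhysiology, d_syn: float) -> float:
    """SF boundary-layer coefficient at the synovium (length scale L_syn), cm/s."""
    return flat_plate_coefficient(phys, d_syn, phys.l_syn_cm)


def k_syn_int(k_bl: float, h_int: float, d_int: float) -> float:
    """Composite SF -> intima coefficient: boundary layer and intima film in series.

    ``h_int`` in cm, ``d_int`` in cm^2/s.  1/k = 1/k_bl + h_int/D_int.
    """
    if k_bl <= 0 or h_int <= 0 or d_int <= 0:
        raise ValueError("k_bl, h_int, d_int must be strictly positive")
    return 1.0 / (1.0 / k_bl + h_int / d_int)


def compute_transport(phys: JointPhysiology, d_syn: float, d_int: float) -> TransportCoefficients:
    """All transfer coefficients for one physiology / compound pairing."""
    l_cart = phys.l_cart_cm
    reynolds, schmidt = reynolds_schmidt(phys, d_syn, l_cart)
    k_sc = k_syn_cart(phys, d_syn)
    k_bl = k_syn_bl(phys, d_syn)
    k_si = k_syn_int(k_bl, phys.intima_thickness * 1e-4, d_int)
    return TransportCoefficients(
        reynolds=reynolds,
        schmidt=schmidt,
        k_syn_cart=k_sc,
        k_syn_bl=k_bl,
        k_syn_int=k_si,
        l_cart=l_cart,
    )
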