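"""Knee-joint physiology: parameter sets, presets, and disease-state scaling.

The joint is described as a synovial-fluid cavity bounded by articular
cartilage (discretised into sublayers) and by the synovium, which is split
into the avascular intima facing the fluid and the vascularised subintima
behind it.  Rheumatoid arthritis (RA) is represented by three changes with
solid literature support: a larger synovial-fluid volume, a thicker intima
(pannus formation) and a thicker subintima (cellular infiltration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

__all__ = [
    "JointPhysiology",
    "healthy_knee_preset",
    "ra_knee_preset",
    "progression_physiology",
    "synovium_volume",
]

# Fields that differ between the healthy and RA presets and are scaled
# during disease progression.
RA_SCALED_FIELDS = ("sf_volume", "intima_thickness", "subintima_thickness")


@dataclass
class JointPhysiology:
    """Anatomical and physiological parameters of one knee state.

    Parameters are stored in their customary reporting units (mL, cm^2, mm,
    µm, cP, K); unit conversion to a coherent cm/mL/h/mg system happens once
    when the ODE system is assembled.

    Attributes
    ----------
    sf_volume : float
        Resident synovial fluid volume, mL.
    sf_ph : float
        Synovial fluid pH.
    sf_viscosity : float
        Dynamic viscosity of synovial fluid, cP.  Governs the hydrodynamic
        boundary layers only; solute diffusivity is set independently on the
        compound (the hyaluronan network raises bulk viscosity without
        hindering small-solute diffusion).
    sf_density : float
        Synovial fluid density, g/mL.
    sf_velocity : float
        Characteristic fluid velocity in the joint space, cm/s.
    synovium_area : float
        Synovial membrane area (intima = subintima), cm^2.
    cartilage_area : float
        Articular cartilage area, cm^2.
    cartilage_thickness : float
        Total cartilage depth, mm.
    n_cartilage_sublayers : int
        Number of equal cartilage shells used in the diffusion stencil.
    intima_thickness : float
        Intima thickness, µm.
    subintima_thickness : float
        Subintima thickness, µm.
    blood_flow_density : float
        Synovial perfusion, mL blood / min / mL synovium.
    temperature : float
        Absolute temperature, K.
    synovial_gap_factor : float
        Ratio of the synovial gap width to the cartilage thickness; sets the
        boundary-layer length scale over the cartilage.
    l_syn : float or None
        Characteristic synovium length scale for the boundary-layer
        correlation at the synovial membrane, cm.  ``None`` means "derive as
        sf_volume / synovium_area" (mean fluid-film height over the
        synovial surface).
    name : str
        Label used in reports.
    """

    sf_volume: float
    sf_ph: float
    sf_viscosity: float
    synovium_area: float
    cartilage_area: float
    cartilage_thickness: float
    intima_thickness: float
    subintima_thickness: float
    blood_flow_density: float
    sf_density: float = 1.0
    sf_velocity: float = 1.5
    n_cartilage_sublayers: int = 10
    temperature: float = 310.15
    synovial_gap_factor: float = 0.207
    l_syn: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        positive = (
            "sf_volume sf_viscosity sf_density sf_velocity synovium_area "
            "cartilage_area cartilage_thickness intima_thickness "
            "subintima_thickness blood_flow_density temperature "
            "synovial_gap_factor"
        ).split()
        for f in positive:
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive, got {getattr(self, f)!r}")
        if not 0 < self.sf_ph < 14:
            raise ValueError(f"sf_ph must lie in (0, 14), got {self.sf_ph!r}")
        if int(self.n_cartilage_sublayers) != self.n_cartilage_sublayers or self.n_cartilage_sublayers < 1:
            raise ValueError("n_cartilage_sublayers must be an integer >= 1")
        self.n_cartilage_sublayers = int(self.n_cartilage_sublayers)
        if self.l_syn is not None and self.l_syn <= 0:
            raise ValueError("l_syn must be positive or None")

    # ------------------------------------------------------------------ #
    # Derived geometry
    # ------------------------------------------------------------------ #
    @property
    def l_cart_cm(self) -> float:
        """Synovial-gap length scale over the cartilage, cm."""
        return self.synovial_gap_factor * self.cartilage_thickness * 0.1  # mm -> cm

    @property
    def l_syn_cm(self) -> float:
        """Boundary-layer length scale at the synovium, cm."""
        if self.l_syn is not None:
            return self.l_syn
        return self.sf_volume / self.synovium_area

    @property
    def cartilage_sublayer_thickness_cm(self) -> float:
        return self.cartilage_thickness * 0.1 / self.n_cartilage_sublayers

    def to_dict(self) -> dict:
        return asdict(self)

    def copy_with(self, **changes) -> "JointPhysiology":
        return replace(self, **changes)


def healthy_knee_preset() -> JointPhysiology:
    """Reference physiology of a healthy adult human knee.

    ``l_syn`` is fixed at the healthy fluid-film height (sf_volume /
    synovium_area of the healthy joint): it is a characteristic length of
    the synovium surface geometry, carried as an explicit parameter so that
    disease-state edits of the fluid volume do not silently change it.
    """
    return JointPhysiology(
        name="healthy",
        sf_volume=2.21,          # mL
        sf_ph=7.7,
        sf_viscosity=389.5,      # cP
        synovium_area=277.0,     # cm^2
        cartilage_area=148.0,    # cm^2
        cartilage_thickness=2.5, # mm
        intima_thickness=18.0,   # µm  (1-2 fibroblast layers)
        subintima_thickness=282.0,  # µm (all capillaries within ~300 µm)
        blood_flow_density=0.63, # mL/min/mL synovium
        l_syn=2.21 / 277.0,      # cm
    )


def ra_knee_preset() -> JointPhysiology:
    """Rheumatoid-arthritis knee: effusion plus synovium thickening.

    SF volume 30 mL (mid-range of 15-60 mL effusions), intima x9
    (8-10 cell layers instead of 1-2), subintima x2.5.  Every other
    parameter keeps its healthy value.
    """
    healthy = healthy_knee_preset()
    return healthy.copy_with(
        name="ra",
        sf_volume=30.0,
        intima_thickness=162.0,
        subintima_thickness=705.0,
    )


def progression_physiology(
    fraction: float,
    breakpoints: dict[str, list[tuple[float, float]]] | None = None,
) -> JointPhysiology:
    """Interpolated physiology between healthy (0) and full RA (1).

    SF volume, intima thickness and subintima thickness are interpolated
    linearly in ``fraction``; everything else stays at the healthy value.
    ``breakpoints`` optionally replaces the linear ramp for any of the three
    scaled parameters with a piecewise-linear table of
    ``(fraction, value)`` knots (endpoints included), so that measured
    stage-specific values can be dropped in when available.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"progression fraction must lie in [0, 1], got {fraction!r}")
    healthy = healthy_knee_preset()
    ra = ra_knee_preset()
    changes: dict[str, float] = {}
    for f in RA_SCALED_FIELDS:
        if breakpoints and f in breakpoints:
            knots = sorted(breakpoints[f])
            xs = [k[0] for k in knots]
            ys = [k[1] for k in knots]
            import numpy as np

            changes[f] = float(np.interp(fraction, xs, ys))
        else:
            lo, hi = getattr(healthy, f), getattr(ra, f)
            changes[f] = lo + fraction * (hi - lo)
    return healthy.copy_with(name=f"progression_{fraction:g}", **changes)


def synovium_volume(phys: JointPhysiology) -> float:
    """Total synovium volume (intima + subintima), mL.

    Used to convert the perfusion density (mL/min/mL synovium) into an
    absolute synovial blood flow.
    """
    thickness_cm = (phys.intima_thickness + phys.subintima_thickness) * 1e-4
    return phys.synovium_area * thickness_cm
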