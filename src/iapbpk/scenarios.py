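"""Disease-progression panels and one-at-a-time parameter sensitivity sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compound import CompoundProperties, mtx_preset
from .icat import DoseEvent, SimulationSettings, simulate
from .metrics import compute_metrics
from .physiology import JointPhysiology, healthy_knee_preset, progression_physiology
from .systemic import SystemicPKParams, mtx_pk_preset

__all__ = [
    "SweepSpec",
    "DEFAULT_PSA_RANGES",
    "default_sweep_values",
    "run_progression_panel",
    "run_psa",
]

SWEEPABLE = ("sf_volume", "intima_thickness", "subintima_thickness", "progression_fraction")

#: Default one-at-a-time ranges: from the healthy baseline to beyond the RA
#: value (SF effusions of 15-60 mL are on record, so the volume sweep runs
#: to 60 mL; thickness sweeps extend past their RA endpoints similarly).
DEFAULT_PSA_RANGES = {
    "sf_volume": (2.21, 60.0),            # mL
    "intima_thickness": (18.0, 300.0),    # µm
    "subintima_thickness": (282.0, 1000.0),  # µm
}

REPORT_COMPARTMENTS = ("plasma", "synovial_fluid", "intima", "subintima")


def default_sweep_values(parameter: str, n_points: int = 8) -> list[float]:
    """Log-spaced sweep values across the default range of one parameter."""
    lo, hi = DEFAULT_PSA_RANGES[parameter]
    return list(np.geomspace(lo, hi, n_points))


@dataclass
class SweepSpec:
    """A one-at-a-time sweep over a physiological parameter.

    ``values`` replace the parameter in ``base`` one run at a time;
    ``progression_fraction`` instead interpolates the whole RA triplet.
    """

    parameter: str
    values: list[float]
    base: JointPhysiology = field(default_factory=healthy_knee_preset)
    t_end: float = 25.0

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"parameter must be one of {SWEEPABLE}, got {self.parameter!r}")
        for v in self.values:
            if self.parameter == "progression_fraction":
                if not 0 <= v <= 1:
                    raise ValueError("progression fractions must lie in [0, 1]")
            elif v <= 0:
                raise ValueError("sweep values must be positive")


def _metric_rows(result, value_label: str, value: float, t_end: float,
                 settings: SimulationSettings) -> list[dict]:
    rows = []
    for comp in REPORT_COMPARTMENTS:
        m = compute_metrics(result.time, result.trace(comp), t_end=t_end,
                            first_obs_time=settings.first_obs_time)
        rows.append(
            {
                value_label: value,
                "compartment": comp,
                "cmax": m.cmax,
                "tmax": m.tmax,
                "auc_0_t": m.auc_0_t,
            }
        )
    return rows


def run_progression_panel(
    fractions: list[float],
    cmpd: CompoundProperties | None = None,
    pk: SystemicPKParams | None = None,
    dose: DoseEvent | None = None,
    settings: SimulationSettings | None = None,
) -> pd.DataFrame:
    """Simulate the case-study dose across RA progression stages.

    Returns a tidy frame with one row per (fraction, compartment) carrying
    Cmax / Tmax / AUC(0 - t_end).
    """
    cmpd = cmpd or mtx_preset()
    pk = pk or mtx_pk_preset()
    dose = dose or DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0)
    settings = settings or SimulationSettings()
    rows: list[dict] = []
    for frac in fractions:
        phys = progression_physiology(frac)
        res = simulate(phys, cmpd, pk, dose, settings)
        rows.extend(_metric_rows(res, "fraction", frac, settings.duration, settings))
    return pd.DataFrame(rows)


def run_psa(
    spec: SweepSpec,
    cmpd: CompoundProperties | None = None,
    pk: SystemicPKParams | None = None,
    dose: DoseEvent | None = None,
    settings: SimulationSettings | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity sweep from a fixed base physiology.

    Each run changes exactly one parameter; results are order-independent
    across the value list.  Returns a tidy long-format frame.
    """
    cmpd = cmpd or mtx_preset()
    pk = pk or mtx_pk_preset()
    dose = dose or DoseEvent(route="IA", amount=5.0, vehicle_volume=2.0)
    settings = settings or SimulationSettings(duration=spec.t_end)
    rows: list[dict] = []
    for value in spec.values:
        if spec.parameter == "progression_fraction":
            phys = progression_physiology(value)
        else:
            phys = spec.base.copy_with(**{spec.parameter: value})
        res = simulate(phys, cmpd, pk, dose, settings)
        for row in _metric_rows(res, "value", value, settings.duration, settings):
            row["parameter"] = spec.parameter
            rows.append(row)
    df = pd.DataFrame(rows)
    return df[["parameter", "value", "compartment", "cmax", "tmax", "auc_0_t"]]
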