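"""Configuration files: physiology / compound / PK parameter sets and run configs.

All files are YAML (JSON is valid YAML and therefore also accepted).  Each
parameter file carries a ``units`` block naming the unit of every field it
declares; units are checked against the ones the model expects, so a file
in the wrong units fails loudly instead of being silently misread.
Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .compound import CompoundProperties, JOINT_TISSUES
from .icat import DoseEvent, SimulationSettings
from .physiology import JointPhysiology
from .systemic import SystemicPKParams

__all__ = [
    "load_physiology",
    "save_physiology",
    "load_compound",
    "save_compound",
    "load_pk_params",
    "save_pk_params",
    "RunConfig",
    "load_run_config",
    "bundled_path",
]

PHYSIOLOGY_UNITS = {
    "sf_volume": "mL",
    "sf_ph": "dimensionless",
    "sf_viscosity": "cP",
    "sf_density": "g/mL",
    "sf_velocity": "cm/s",
    "synovium_area": "cm^2",
    "cartilage_area": "cm^2",
    "cartilage_thickness": "mm",
    "n_cartilage_sublayers": "count",
    "intima_thickness": "um",
    "subintima_thickness": "um",
    "blood_flow_density": "mL/min/mL",
    "temperature": "K",
    "synovial_gap_factor": "dimensionless",
    "l_syn": "cm",
}

COMPOUND_UNITS = {
    "log_p": "dimensionless",
    "log_d_74": "dimensionless",
    "d_aqueous": "cm^2/s",
    "reference_solubility": "mg/mL",
    "reference_solubility_ph": "dimensionless",
    "fup": "fraction",
    "rbp": "dimensionless",
    "fu_tissue": "fraction",
    "molecular_radius": "nm",
    "particle_radius": "um",
    "precipitate_radius": "um",
    "particle_density": "g/mL",
    "mean_precipitation_time": "s",
    "pka_list": "dimensionless",
    "diffusivity_mode": "enum",
}

PK_UNITS = {
    "cl_renal": "mL/h/kg",
    "vc": "mL/kg",
    "k12": "1/h",
    "k21": "1/h",
    "k13": "1/h",
    "k31": "1/h",
    "body_weight": "kg",
}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _read(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def _check(data: dict, expected_units: dict, kind: str, source: str) -> dict:
    data = dict(data)
    name = data.pop("name", None)
    units = data.pop("units", {}) or {}
    unknown = set(data) - set(expected_units)
    if unknown:
        raise ConfigError(f"{source}: unknown {kind} keys {sorted(unknown)}")
    for field_name, unit in units.items():
        if field_name not in expected_units:
            raise ConfigError(f"{source}: units given for unknown field {field_name!r}")
        if unit != expected_units[field_name]:
            raise ConfigError(
                f"{source}: field {field_name!r} must be given in "
                f"{expected_units[field_name]!r}, file declares {unit!r}"
            )
    if name is not None:
        data["name"] = name
    return data


def load_physiology(path: str | Path) -> JointPhysiology:
    data = _check(_read(path), PHYSIOLOGY_UNITS, "physiology", str(path))
    try:
        return JointPhysiology(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_physiology(phys: JointPhysiology, path: str | Path) -> None:
    data = {"name": phys.name, "units": dict(PHYSIOLOGY_UNITS)}
    data.update({k: v for k, v in phys.to_dict().items() if k != "name"})
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_compound(path: str | Path) -> CompoundProperties:
    data = _check(_read(path), COMPOUND_UNITS, "compound", str(path))
    if "pka_list" in data and data["pka_list"]:
        data["pka_list"] = [(float(p), str(k)) for p, k in data["pka_list"]]
    try:
        return CompoundProperties(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_compound(cmpd: CompoundProperties, path: str | Path) -> None:
    data = {"name": cmpd.name, "units": dict(COMPOUND_UNITS)}
    d = cmpd.to_dict()
    d.pop("name")
    d["pka_list"] = [list(t) for t in d["pka_list"]]
    data.update(d)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_pk_params(path: str | Path, body_weight: float | None = None) -> SystemicPKParams:
    data = _check(_read(path), PK_UNITS, "PK", str(path))
    data.pop("name", None)
    if body_weight is not None:
        data["body_weight"] = body_weight
    try:
        return SystemicPKParams(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_pk_params(pk: SystemicPKParams, path: str | Path) -> None:
    data = {"units": dict(PK_UNITS)}
    data.update(pk.to_dict())
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def bundled_path(filename: str) -> Path:
    """Path of a data file shipped with the package (presets, run configs)."""
    ref = resources.files("iapbpk").joinpath("data", filename)
    return Path(str(ref))


def _resolve(ref: str, base_dir: Path) -> Path:
    """Resolve a file reference relative to the run config, then the bundle."""
    p = Path(ref)
    if p.is_absolute() and p.exists():
        return p
    local = base_dir / p
    if local.exists():
        return local
    bundled = bundled_path(ref)
    if bundled.exists():
        return bundled
    raise ConfigError(f"cannot resolve referenced file: {ref}")


@dataclasses.dataclass
class RunConfig:
    """A fully resolved simulation run."""

    physiology: JointPhysiology
    compound: CompoundProperties
    pk: SystemicPKParams
    dose: DoseEvent
    settings: SimulationSettings
    output_prefix: str = "run"
    seed: int = 0


RUN_KEYS = {"physiology", "compound", "pk", "dose", "settings", "output_prefix", "seed"}
DOSE_KEYS = {"route", "amount", "vehicle_volume", "time", "form"}
SETTINGS_KEYS = {"duration", "output_step", "rtol", "atol", "q_volume_convention",
                 "first_obs_time", "allow_precipitation", "boundary_layer_diffusivity"}


def load_run_config(path: str | Path) -> RunConfig:
    """Load a run file referencing physiology / compound / PK parameter files.

    References are looked up relative to the run file first, then among the
    bundled presets, so `physiology: ra_knee.yaml` works out of the box.
    """
    path = Path(path)
    data = _read(path)
    unknown = set(data) - RUN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown run-config keys {sorted(unknown)}")
    for required in ("physiology", "compound", "pk", "dose"):
        if required not in data:
            raise ConfigError(f"{path}: missing required key {required!r}")
    base = path.parent

    phys = load_physiology(_resolve(data["physiology"], base))

    cmpd = load_compound(_resolve(data["compound"], base))

    pk_block = data["pk"]
    if isinstance(pk_block, str):
        pk = load_pk_params(_resolve(pk_block, base))
    else:
        ref = pk_block.get("file")
        bw = pk_block.get("body_weight")
        if ref is None:
            raise ConfigError(f"{path}: pk block needs a 'file' reference")
        pk = load_pk_params(_resolve(ref, base), body_weight=bw)

    dose_block = dict(data["dose"])
    unknown = set(dose_block) - DOSE_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown dose keys {sorted(unknown)}")
    try:
        dose = DoseEvent(**dose_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: dose: {exc}") from exc

    settings_block = dict(data.get("settings") or {})
    unknown = set(settings_block) - SETTINGS_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown settings keys {sorted(unknown)}")
    try:
        settings = SimulationSettings(**settings_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: settings: {exc}") from exc

    return RunConfig(
        physiology=phys,
        compound=cmpd,
        pk=pk,
        dose=dose,
        settings=settings,
        output_prefix=str(data.get("output_prefix", path.stem)),
        seed=int(data.get("seed", 0)),
    )
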