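"""Run configuration: strict YAML loading onto the parameter dataclasses.

One YAML file configures a run. Sections map onto the parameter blocks
(soil, canopy, gas_exchange, hydraulics, carbon, berry, biomass) plus
run-level settings; unknown keys are rejected with the offending section
and key named, and a round-trip save/load is the identity. The fourteen
recalibrated quantities live in their blocks with defaults; everything
else is a documented fixed constant carried from the pre-existing
parameterization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .berry import BerryParams
from .canopy import CanopyConfig
from .carbon import CarbonParams, OrganBiomass
from .environment import SoilParams
from .leaf import GasExchangeParams
from .plant import HydraulicParams, PlantParams

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "CALIBRATED_PARAMETERS"]

#: the 14 recalibrated quantities and the block each lives in
CALIBRATED_PARAMETERS = {
    "soil": ("ks", "alpha_v", "n", "p", "rsc"),
    "canopy": ("leafN_content",),
    "gas_exchange": ("slope_vcmax", "psi50_leaf"),
    "berry": ("vmax_berry", "km_berry", "lp_max", "lp_min", "fm_star", "k_lp"),
}

_SECTION_TYPES = {
    "soil": SoilParams,
    "canopy": CanopyConfig,
    "gas_exchange": GasExchangeParams,
    "hydraulics": HydraulicParams,
    "carbon": CarbonParams,
    "berry": BerryParams,
    "biomass": OrganBiomass,
}


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    soil: SoilParams = field(default_factory=SoilParams)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    gas_exchange: GasExchangeParams = field(default_factory=GasExchangeParams)
    hydraulics: HydraulicParams = field(default_factory=HydraulicParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    berry: BerryParams = field(default_factory=BerryParams)
    biomass: OrganBiomass = field(default_factory=OrganBiomass)
    berries_per_shoot: float = 80.0
    c_par: float = 2.1
    seed: int = 0
    log_level: str = "INFO"
    scenario_shifts: tuple[int, ...] = (14, 28)
    paths: dict = field(default_factory=dict)

    def plant_params(self) -> PlantParams:
        return PlantParams(
            soil=self.soil,
            canopy=self.canopy,
            gx=self.gas_exchange,
            hydraulics=self.hydraulics,
            carbon=self.carbon,
            berry=self.berry,
            biomass=self.biomass,
            berries_per_shoot=self.berries_per_shoot,
            c_par=self.c_par,
        )


_RUN_LEVEL_KEYS = {
    "berries_per_shoot",
    "c_par",
    "seed",
    "log_level",
    "scenario_shifts",
    "paths",
}


def _build_section(name: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"section {name!r}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    # tuple-typed fields arrive as lists from YAML
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration from YAML (or a dict).

    Missing sections and keys take their documented defaults; unknown
    sections or keys are rejected by name.
    """
    if data is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTION_TYPES) - _RUN_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration section(s)/key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        section = data.get(name, {})
        if section is None:
            section = {}
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(name, cls, section)
    for key in _RUN_LEVEL_KEYS:
        if key in data:
            v = data[key]
            kwargs[key] = tuple(v) if key == "scenario_shifts" else v
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _to_dict(cfg: RunConfig) -> dict:
    out: dict = {}
    for name, cls in _SECTION_TYPES.items():
        block = dataclasses.asdict(getattr(cfg, name))
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in block.items()
        }
    for key in sorted(_RUN_LEVEL_KEYS):
        v = getattr(cfg, key if key != "scenario_shifts" else "scenario_shifts")
        out[key] = list(v) if isinstance(v, tuple) else v
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the full (defaulted) configuration; load(save(cfg)) == cfg."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the full configuration, for output provenance."""
    blob = json.dumps(_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
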