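"""Run settings: defaults, YAML loading, and the convention switches.

A settings file is YAML with either nested sections or flat dotted keys::

    medium:
      conductivity_S_per_m: 6.0e-3
    field.geometry_factor: 0.3
    conventions.crossover_prefactor: sqrt2

Every numeric result of the pipeline depends on the conventions block, so the
full settings are echoed into all output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .electro_model import (
    CellElectricalModel,
    Conventions,
    FieldModel,
    MediumProperties,
    PhysicalContext,
    RampProtocol,
)

__all__ = ["CellDefaults", "Settings", "default_settings", "load_settings"]


@dataclass(frozen=True)
class CellDefaults:
    """Population-level cell parameters used to build representative cells."""

    radius_mean_m: float = 10e-6
    radius_sd_m: float = 1e-6
    crossover_mean_hz: float = 20e3
    crossover_sd_hz: float = 2e3
    rho_cyt_ohm_m: float = 2.0
    eps_cyto: float = 80.0
    eps_mem: float = 5.0

    def representative_cell(self, condition: str = "untreated") -> CellElectricalModel:
        """A cell at the population mean (used for tension conversion)."""
        return CellElectricalModel(
            radius_m=self.radius_mean_m,
            crossover_hz=self.crossover_mean_hz,
            rho_cyt_ohm_m=self.rho_cyt_ohm_m,
            eps_cyto=self.eps_cyto,
            eps_mem=self.eps_mem,
            cell_id="representative",
            condition=condition,
        )


@dataclass(frozen=True)
class Settings:
    """Complete, self-describing parameter set for a run."""

    medium: MediumProperties = field(default_factory=MediumProperties)
    cell: CellDefaults = field(default_factory=CellDefaults)
    field_model: FieldModel = field(default_factory=FieldModel)
    protocol: RampProtocol = field(default_factory=RampProtocol)
    physics: PhysicalContext = field(default_factory=PhysicalContext)
    conventions: Conventions = field(default_factory=Conventions)

    def to_dict(self) -> dict:
        return {
            "medium": asdict(self.medium),
            "cell": asdict(self.cell),
            "field": asdict(self.field_model),
            "protocol": asdict(self.protocol),
            "physics": asdict(self.physics),
            "conventions": self.conventions.to_dict(),
        }


def default_settings() -> Settings:
    return Settings()


_SECTION_TYPES = {
    "medium": MediumProperties,
    "cell": CellDefaults,
    "field": FieldModel,
    "protocol": RampProtocol,
    "physics": PhysicalContext,
    "conventions": Conventions,
}
_SECTION_ATTR = {
    "medium": "medium",
    "cell": "cell",
    "field": "field_model",
    "protocol": "protocol",
    "physics": "physics",
    "conventions": "conventions",
}


def _unflatten(mapping: Mapping[str, Any]) -> dict[str, dict[str, Any]]:
    out: dict[str, dict[str, Any]] = {}
    for key, value in mapping.items():
        if isinstance(value, Mapping):
            out.setdefault(key, {}).update(value)
        elif "." in key:
            section, sub = key.split(".", 1)
            out.setdefault(section, {})[sub] = value
        else:
            raise ValueError(f"unrecognised top-level settings key {key!r}")
    return out


def settings_from_mapping(mapping: Mapping[str, Any]) -> Settings:
    """Build :class:`Settings` from a (possibly flat-keyed) mapping of overrides."""
    sections = _unflatten(mapping)
    unknown = set(sections) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown settings sections: {sorted(unknown)}")
    kwargs = {}
    for section, overrides in sections.items():
        cls = _SECTION_TYPES[section]
        base = cls()
        bad = set(overrides) - set(base.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
        kwargs[_SECTION_ATTR[section]] = replace(base, **overrides)
    return Settings(**kwargs)


def load_settings(path: str | Path) -> Settings:
    """Load settings overrides from a YAML file; omitted keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"settings file {path} must contain a mapping")
    return settings_from_mapping(data)
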