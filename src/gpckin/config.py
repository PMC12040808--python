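"""Per-organism cultivation configuration and its loaders.

One :class:`OrganismConfig` bundles everything the pipeline needs to know
about a cultivation: bottle geometry, temperature, the per-cycle pressure
drop the gas controller enforces, the OD578-to-dry-mass coefficient, and the
trimming variables (``calculation``, ``average``, ``move_max``, ``min_pressure``,
``len_cycles``, ``pressure_drop_min``) that steer the data-cleaning filters.

The trimming variables are expressed in data points at the configured
sampling interval (10 s by default), matching how gas-controller logs are
recorded.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["OrganismConfig", "load_config", "PRESETS"]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1


class ConfigError(ValueError):
    """A configuration value violates an invariant."""


@dataclass
class OrganismConfig:
    """Cultivation parameters and trimming variables for one organism.

    Attributes
    ----------
    name : str
        Strain label.
    temperature : float
        Cultivation temperature, deg C.
    ph : float
        Medium pH (informational; not used in calculations).
    v_culture : float
        Culture (liquid) volume, mL.
    v_headspace : float
        Total gas volume (bottle headspace plus tubing), mL.
    delta_p_cycle : float
        Programmed absolute pressure drop per methanation cycle, bar.
    alpha_od : float or None
        Dry biomass per OD578 unit, g L^-1; ``None`` if not determined.
    calculation : int
        Number of consecutive points per rate-calculation window.
    average : int
        Width of the centred moving-mean smoothing window (1 = off).
    move_max : int
        Points erased after the peak of each cycle (0 = off).
    min_pressure : float
        Absolute floor, mbar: points below it are discarded (filter i).
    len_cycles : int
        Minimum cycle length in points (filter iii).
    pressure_drop_min : float
        Minimum per-cycle pressure drop, mbar, implying catalytic
        activity (filter iv); default 50.
    refill_threshold : float
        Cumulative monotone pressure rise, mbar, that marks a
        re-pressurization and hence a cycle boundary.
    sample_interval : float
        Logging interval, s.
    sample_draw : float
        Liquid withdrawn per sampling event, mL; moves from culture to
        headspace volume after each sampled cycle.
    gas_constant : float
        J mol^-1 K^-1.
    """

    name: str
    temperature: float
    ph: float
    v_culture: float
    v_headspace: float
    delta_p_cycle: float
    alpha_od: float | None = None
    calculation: int = 30
    average: int = 1
    move_max: int = 0
    min_pressure: float = 1100.0
    len_cycles: int = 10
    pressure_drop_min: float = 50.0
    refill_threshold: float = 200.0
    sample_interval: float = 10.0
    sample_draw: float = 0.7
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.v_culture <= 0:
            raise ConfigError(f"v_culture must be > 0 mL, got {self.v_culture}")
        if self.v_headspace <= 0:
            raise ConfigError(f"v_headspace must be > 0 mL, got {self.v_headspace}")
        if self.temperature <= -273.15:
            raise ConfigError(f"temperature must exceed absolute zero, got {self.temperature}")
        if self.delta_p_cycle <= 0:
            raise ConfigError(f"delta_p_cycle must be > 0 bar, got {self.delta_p_cycle}")
        for name in ("calculation", "average", "len_cycles"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
            setattr(self, name, int(v))
        if int(self.move_max) != self.move_max or self.move_max < 0:
            raise ConfigError(f"move_max must be an integer >= 0, got {self.move_max!r}")
        self.move_max = int(self.move_max)
        if self.pressure_drop_min <= 0:
            raise ConfigError(f"pressure_drop_min must be > 0 mbar, got {self.pressure_drop_min}")
        if self.sample_interval <= 0:
            raise ConfigError(f"sample_interval must be > 0 s, got {self.sample_interval}")
        if self.refill_threshold <= 0:
            raise ConfigError(f"refill_threshold must be > 0 mbar, got {self.refill_threshold}")
        if self.alpha_od is not None and self.alpha_od <= 0:
            raise ConfigError(f"alpha_od must be > 0 when given, got {self.alpha_od}")

    @property
    def temperature_K(self) -> float:
        return self.temperature + 273.15

    def stop_pressure(self, start_pressure: float) -> float:
        """Cycle stop threshold: start pressure minus the programmed drop."""
        return start_pressure - self.delta_p_cycle * 1000.0

    def replace(self, **kw) -> "OrganismConfig":
        return replace(self, **kw)


# Published per-organism parameterizations (trimming variables in points).
PRESETS: dict[str, OrganismConfig] = {
    "M. marburgensis": OrganismConfig(
        name="M. marburgensis", temperature=65.0, ph=7.0, v_culture=30.0,
        v_headspace=38.228, delta_p_cycle=1.0, alpha_od=0.393,
        calculation=129, average=1, move_max=0,
    ),
    "M. igneus": OrganismConfig(
        name="M. igneus", temperature=88.0, ph=5.7, v_culture=30.0,
        v_headspace=44.889, delta_p_cycle=0.5, alpha_od=0.429,
        calculation=10, average=9, move_max=1,
    ),
    "M. villosus": OrganismConfig(
        name="M. villosus", temperature=80.0, ph=6.5, v_culture=30.0,
        v_headspace=38.228, delta_p_cycle=0.5, alpha_od=0.334,
        calculation=10, average=9, move_max=5,
    ),
    "M. jannaschii": OrganismConfig(
        name="M. jannaschii", temperature=85.0, ph=6.0, v_culture=30.0,
        v_headspace=44.889, delta_p_cycle=0.5, alpha_od=0.635,
        calculation=65, average=1, move_max=0,
    ),
    "M. maripaludis": OrganismConfig(
        name="M. maripaludis", temperature=37.0, ph=6.9, v_culture=204.175,
        v_headspace=1006.025, delta_p_cycle=1.0, alpha_od=None,
        calculation=30, average=30, move_max=0,
    ),
}

_REQUIRED_KEYS = ("name", "temperature", "ph", "v_culture", "v_headspace", "delta_p_cycle")
_OPTIONAL_KEYS = (
    "alpha_od", "calculation", "average", "move_max", "min_pressure",
    "len_cycles", "pressure_drop_min", "refill_threshold",
    "sample_interval", "sample_draw", "gas_constant",
)


def _config_from_mapping(doc: dict) -> OrganismConfig:
    missing = [k for k in _REQUIRED_KEYS if k not in doc or doc[k] in (None, "")]
    if missing:
        raise ConfigError(f"config missing required field(s): {', '.join(missing)}")
    unknown = set(doc) - set(_REQUIRED_KEYS) - set(_OPTIONAL_KEYS)
    if unknown:
        raise ConfigError(f"unknown config field(s): {', '.join(sorted(unknown))}")
    kwargs = {"name": str(doc["name"])}
    for k in _REQUIRED_KEYS[1:]:
        kwargs[k] = float(doc[k])
    for k in _OPTIONAL_KEYS:
        if k in doc and doc[k] not in (None, "", "-"):
            kwargs[k] = float(doc[k]) if k not in ("calculation", "average", "move_max", "len_cycles") else int(doc[k])
    return OrganismConfig(**kwargs)


def load_config(path) -> list[OrganismConfig]:
    """Load organism configurations from a YAML (or CSV) file.

    The YAML file may hold a single mapping, a list of mappings, or multiple
    documents, one organism each.  A CSV file needs a header row with the
    same field names.  Defaults are applied for every optional trimming
    variable; invariant violations raise :class:`ConfigError` naming the
    offending field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".csv":
        reader = csv.DictReader(io.StringIO(text))
        docs = [dict(row) for row in reader]
    else:
        loaded = [d for d in yaml.safe_load_all(text) if d is not None]
        docs = []
        for d in loaded:
            if isinstance(d, list):
                docs.extend(d)
            elif isinstance(d, dict):
                docs.append(d)
            else:
                raise ConfigError(f"cannot interpret config document of type {type(d).__name__}")
    if not docs:
        raise ConfigError(f"no organism configuration found in {path}")
    return [_config_from_mapping(d) for d in docs]
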