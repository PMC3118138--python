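"""YAML configuration loading.

The packaged ``data/defaults.yaml`` holds every default (kinetic parameters,
biomass composition, initial benchmark medium); a user config file overrides
any subset of keys.  Unknown keys are rejected with the offending key named.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .errors import ConfigError
from .kinetics import BiomassComposition, KineticParameters, NitrogenCompound
from .simulate import SimulationConfig
from .state import FermentationState

_CONFIG_KEYS = {
    "step", "temperature", "sugar_threshold", "N_exhaust", "max_time",
    "params", "composition", "nitrogen_compounds", "initial",
    "biomass_reaction", "maintenance_reaction",
    "apply_anaerobic", "enable_quinones", "complete_tca", "allow_oxygen",
    "limit_sterols", "legacy_maintenance", "legacy_biomass",
    "zero_maintenance", "unbounded_maintenance", "bilevel_tol",
}


def packaged_defaults() -> dict:
    text = resources.files("dynafba").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> tuple[SimulationConfig, FermentationState]:
    """Build a SimulationConfig and initial state from defaults plus an
    optional user YAML file."""
    raw = packaged_defaults()
    if path is not None:
        with open(str(path)) as fh:
            user = yaml.safe_load(fh) or {}
        for key in user:
            if key not in _CONFIG_KEYS:
                raise ConfigError(f"unknown configuration key {key!r}")
        raw = _deep_merge(raw, user)

    try:
        params = KineticParameters.from_dict(raw.get("params", {}))
    except TypeError as exc:
        raise ConfigError(f"bad kinetic parameter block: {exc}") from exc
    comp = raw.get("composition", {})
    try:
        composition = BiomassComposition(**comp)
    except TypeError as exc:
        raise ConfigError(f"bad composition block: {exc}") from exc
    compounds = [
        NitrogenCompound(c["species"], float(c["mg_n_per_mmol"]))
        for c in raw.get("nitrogen_compounds", [])
    ]

    from .toy import TOY_PRECURSORS, biomass_carbon_fraction

    temperature = raw["temperature"]
    if isinstance(temperature, list):
        temperature = [(float(a), float(b)) for a, b in temperature]
    config = SimulationConfig(
        step=float(raw["step"]),
        temperature=temperature,
        sugar_threshold=float(raw["sugar_threshold"]),
        N_exhaust=float(raw["N_exhaust"]),
        max_time=float(raw["max_time"]),
        params=params,
        composition=composition,
        precursors=TOY_PRECURSORS,
        nitrogen_compounds=compounds,
        biomass_reaction=raw.get("biomass_reaction", "BIOMASS"),
        maintenance_reaction=raw.get("maintenance_reaction", "ATPM"),
        apply_anaerobic=bool(raw.get("apply_anaerobic", True)),
        enable_quinones=bool(raw.get("enable_quinones", False)),
        complete_tca=bool(raw.get("complete_tca", False)),
        allow_oxygen=bool(raw.get("allow_oxygen", False)),
        limit_sterols=bool(raw.get("limit_sterols", False)),
        legacy_maintenance=bool(raw.get("legacy_maintenance", False)),
        legacy_biomass=bool(raw.get("legacy_biomass", False)),
        zero_maintenance=bool(raw.get("zero_maintenance", False)),
        unbounded_maintenance=bool(raw.get("unbounded_maintenance", False)),
        bilevel_tol=float(raw.get("bilevel_tol", 1e-6)),
        carbon_fraction_fn=biomass_carbon_fraction,
    )
    init = raw.get("initial", {})
    state = FermentationState(
        t=0.0,
        T=float(init.get("temperature", 28.0)),
        X_V=float(init.get("biomass", 0.1)),
        M_EX={k: float(v) for k, v in init.get("concentrations", {}).items()},
    )
    return config, state
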