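"""Run configuration: one YAML file covering simulation, MCMC and grids.

Unknown keys are rejected so typos cannot silently fall back to
defaults; every CLI run writes its fully resolved configuration next to
its outputs, which together with the seed reproduces the run
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .sampler import McmcConfig
from .simulate import SimulationConfig

_SECTIONS = {
    "simulation": SimulationConfig,
    "mcmc": McmcConfig,
}
_GRID_KEYS = {"sp_grid", "m_grid", "n_replicates", "methods"}


class ConfigError(ValueError):
    """Malformed run configuration."""


def load_config(path) -> dict:
    """Load a YAML config, rejecting unknown sections and keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    out = {}
    for section, payload in raw.items():
        if section == "grid":
            unknown = set(payload) - _GRID_KEYS
            if unknown:
                raise ConfigError(f"unknown keys in grid section: {sorted(unknown)}")
            out["grid"] = dict(payload)
        elif section in _SECTIONS:
            cls = _SECTIONS[section]
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(payload) - known
            if unknown:
                raise ConfigError(f"unknown keys in {section} section: {sorted(unknown)}")
            out[section] = dict(payload)
        else:
            raise ConfigError(f"unknown config section {section!r}; "
                              f"expected one of {sorted([*_SECTIONS, 'grid'])}")
    return out


def dump_resolved(config: dict, path) -> None:
    """Write the fully resolved configuration used by a run."""
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            obj = dataclasses.asdict(obj)
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()
                    if not isinstance(v, type) and k != "sign"}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if hasattr(obj, "item"):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=True))
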