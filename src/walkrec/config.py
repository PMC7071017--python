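"""YAML-backed runtime configuration with the pipeline's documented defaults."""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS = {
    "madgwick": {"gamma": 0.05, "mu": None, "q_init": "identity"},
    "filter": {"order": 10, "cutoff_hz": 3.0},
    "window": {"n": 250, "overlap": 0.5, "purity": 0.75},
    "features": {"energy_squared": False, "min_prominence": 0.0},
    "elastic": {"half": "first"},
    "io": {"rate_hz": 100.0, "column_map": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file (deep-merged)."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, user)
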