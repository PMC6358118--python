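"""Hierarchical YAML run configuration.

Selects the world seed/resolution, climate scenario, solver tolerances,
PIM parameters, and feedback settings; unspecified keys fall back to the
package defaults so a config file only needs the keys it overrides.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Optional

import yaml

DEFAULTS: dict = {
    "world": {"seed": 1, "n_subregions": 8, "n_commodities": 7, "horizon": 2030},
    "climate": "CC",
    "solver": {"tol": 1e-10, "max_iter": 200},
    "pim": {"decay": 0.10, "spillover": 0.2},
    "feedback": {"kappa": None, "tol": 1e-8, "max_iter": 50},
    "comp": {"margin_reduction": 0.20},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[Path] = None) -> dict:
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _merge(DEFAULTS, user)
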