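"""Loading and merging of the model parameter file.

The shipped ``data/default_params.yaml`` holds every kinetic constant,
compartment volume, conductance and light-model default.  A user file with
the same structure (partial is fine) is merged on top of it.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_params", "default_params_text"]


def default_params_text() -> str:
    return (resources.files("c4sim") / "data" / "default_params.yaml").read_text()


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_params(path: str | Path | None = None) -> dict:
    """Default parameter set, optionally overlaid with a user YAML file."""
    params = yaml.safe_load(default_params_text())
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        params = _deep_merge(params, user)
    return params
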