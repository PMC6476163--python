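"""Flat config-file round-tripping for parameter bundles.

Configs are flat key-value YAML or JSON files using exactly the keys
``b, b_prime, K, phi, d, d_prime, beta, m, eta, p, q, q_l, gamma, alpha``;
keys that do not apply to a model are written as null and ignored on read.
Floats round-trip bit-for-bit in both dialects.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .parameters import StrategyParameters, params_from_dict, params_to_dict

__all__ = ["read_params", "write_params"]


def write_params(params: StrategyParameters, path) -> None:
    """Serialize a bundle to YAML (default) or JSON, chosen by suffix."""
    path = Path(path)
    flat = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(flat, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=False))


def read_params(model_id: str, path) -> StrategyParameters:
    """Load a bundle for ``model_id`` from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} does not contain a key-value mapping")
    return params_from_dict(model_id, raw)
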