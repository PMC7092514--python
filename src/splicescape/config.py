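"""Structured run configuration with study-default thresholds.

One YAML file drives every pipeline stage; all analysis thresholds
(probability > 0.95, |ΔPSI| ≥ 0.1, GO parent depth-1 rollup with the 2%
genome filter, TPM on/off cutoffs) live here so sensitivity analyses are a
config edit, not a code change.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "n_genes": 60,
        "n_chromosomes": 4,
        "n_per_cell": 12,
        "effect_fraction": 0.05,
        "effect_size_range": [0.15, 0.5],
        "psi_concentration": 24.0,
        "convergence_factor": 0.5,
        "n_exclusive_isoforms": 0,
    },
    "delta": {
        "n_boot": 10000,
        "method": "bootstrap",
        "prob_min": 0.95,
        "dpsi_min": 0.1,
    },
    "landscape": {
        "bins": 20,
    },
    "exons": {
        "whole_exon": False,
        "motifs": {"double-basic": "[KR][KR]", "zinc-knuckle": "C..C"},
    },
    "go": {
        "min_genome_fraction": 0.02,
    },
    "annotation": {
        "isoform_policy": "all",
    },
    "tpm": {
        "on_min": 1.0,
        "off_max": 0.1,
        "min_frac": 0.75,
    },
}

_NUMERIC = (int, float)
_SCHEMA: dict[tuple[str, ...], type | tuple] = {
    ("seed",): _NUMERIC,
    ("simulate", "n_genes"): _NUMERIC,
    ("simulate", "n_chromosomes"): _NUMERIC,
    ("simulate", "n_per_cell"): _NUMERIC,
    ("simulate", "effect_fraction"): _NUMERIC,
    ("simulate", "effect_size_range"): list,
    ("simulate", "psi_concentration"): _NUMERIC,
    ("simulate", "convergence_factor"): _NUMERIC,
    ("simulate", "n_exclusive_isoforms"): _NUMERIC,
    ("delta", "n_boot"): _NUMERIC,
    ("delta", "method"): str,
    ("delta", "prob_min"): _NUMERIC,
    ("delta", "dpsi_min"): _NUMERIC,
    ("landscape", "bins"): _NUMERIC,
    ("exons", "whole_exon"): bool,
    ("exons", "motifs"): dict,
    ("go", "min_genome_fraction"): _NUMERIC,
    ("annotation", "isoform_policy"): str,
    ("tpm", "on_min"): _NUMERIC,
    ("tpm", "off_max"): _NUMERIC,
    ("tpm", "min_frac"): _NUMERIC,
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Reject unknown keys and wrong value types, listing every offender."""
    errors = []
    known_sections = {k[0] for k in _SCHEMA}
    for section, value in cfg.items():
        if section not in known_sections:
            errors.append(f"unknown section {section!r}")
            continue
        if (section,) in _SCHEMA:
            if not isinstance(value, _SCHEMA[(section,)]):
                errors.append(f"{section}: wrong type")
            continue
        if not isinstance(value, Mapping):
            errors.append(f"{section}: expected a mapping")
            continue
        for key, v in value.items():
            path = (section, key)
            if path not in _SCHEMA:
                errors.append(f"unknown key {section}.{key}")
            elif not isinstance(v, _SCHEMA[path]):
                errors.append(f"{section}.{key}: wrong type {type(v).__name__}")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(sorted(errors)))


def load_config(path: str | Path | None = None, **overrides: Any) -> dict[str, Any]:
    """Merge defaults ← YAML file ← keyword overrides and validate."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg
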