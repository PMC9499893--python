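"""Key-value configuration files (YAML mappings).

A single flat mapping addresses every model constant by its published name
(D_a, D_n, D_ADP, R_ADP, ADP_t, t_ADP, C, alpha, beta, phi_a0, phi_b0),
every solver control, the synthetic-flow recipe and the sweep specification.
Unknown keys are errors — a silently ignored typo in, say, ``alpha`` would
corrupt a sensitivity study.
"""

from __future__ import annotations

from dataclasses import fields as dataclass_fields
from typing import Dict, Tuple

import yaml

from .errors import ConfigurationError
from .fields import ModelParameters
from .synthetic import FlowRecipe

__all__ = ["load_config", "params_from_config", "recipe_from_config", "KNOWN_KEYS"]

_PARAM_KEYS = tuple(f.name for f in dataclass_fields(ModelParameters))
_RECIPE_KEYS = tuple(f.name for f in dataclass_fields(FlowRecipe))
_EXTRA_KEYS = ("n_regions", "sweep")

KNOWN_KEYS = frozenset(_PARAM_KEYS) | frozenset(_RECIPE_KEYS) | frozenset(_EXTRA_KEYS)


def load_config(path) -> Dict:
    """Load and key-validate a flat YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config must be a key-value mapping, got {type(cfg).__name__}")
    unknown = sorted(set(cfg) - KNOWN_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    return cfg


def params_from_config(cfg: Dict) -> ModelParameters:
    """Model parameters from a config mapping; unset keys keep their defaults."""
    kwargs = {k: cfg[k] for k in _PARAM_KEYS if k in cfg}
    return ModelParameters(**kwargs)


def recipe_from_config(cfg: Dict) -> Tuple[FlowRecipe, int]:
    """Flow recipe and region count from a config mapping."""
    kwargs = {k: cfg[k] for k in _RECIPE_KEYS if k in cfg}
    return FlowRecipe(**kwargs), int(cfg.get("n_regions", 4))
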