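"""Structured-text (YAML) configuration for policies and designs.

Unknown keys are rejected so that typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import yaml

from .orthography import CodingPolicy, ValidationError
from .simulate import DesignSpec

__all__ = ["load_config", "policy_from_dict", "design_from_dict"]

_POLICY_KEYS = {"max_gap", "include_edges", "gap_weights", "noise_sd", "preset"}
_DESIGN_KEYS = {
    "n_subjects",
    "n_items",
    "condition_effects",
    "control",
    "baseline_rt_ms",
    "reps",
    "p_same",
    "subject_sd",
    "item_sd",
    "residual_sd",
    "error_rates",
    "seed",
}


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], what: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValidationError(f"unknown {what} keys: {sorted(unknown)}")


def policy_from_dict(data: Mapping[str, Any]) -> CodingPolicy:
    """Build a :class:`CodingPolicy` from a config mapping.

    ``preset: seriol`` starts from the distance-weighted preset; all other
    keys override fields directly.
    """
    _reject_unknown(data, _POLICY_KEYS, "policy")
    preset = data.get("preset")
    if preset not in (None, "binary", "seriol"):
        raise ValidationError(f"unknown policy preset {preset!r}")
    base: dict[str, Any] = {}
    if preset == "seriol":
        base = {"max_gap": 2, "gap_weights": {0: 1.0, 1: 0.8, 2: 0.4}}
    for key in ("max_gap", "include_edges", "noise_sd"):
        if key in data:
            base[key] = data[key]
    if "gap_weights" in data:
        base["gap_weights"] = {int(g): float(w) for g, w in data["gap_weights"].items()}
    return CodingPolicy(**base)


def design_from_dict(data: Mapping[str, Any]) -> DesignSpec:
    _reject_unknown(data, _DESIGN_KEYS, "design")
    if "seed" not in data:
        raise ValidationError("design config must set an explicit seed")
    return DesignSpec(**data)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config file; top-level sections are returned as-is."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError("config file must contain a mapping at top level")
    return data
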