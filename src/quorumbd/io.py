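"""Configuration handling and CSV/JSON serialization.

Runs are configured by a flat key-value file (a YAML-compatible subset:
scalars and plain lists only).  Every run writes its fully resolved
configuration — defaults filled in — beside its outputs, and loading that
resolved file reproduces the run exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from .params import ModelParameters, SignalingMode, Strategy
from .solvers import SolutionField

__all__ = [
    "MODEL_KEYS",
    "COMMAND_KEYS",
    "ConfigError",
    "load_config",
    "resolve_config",
    "write_resolved_config",
    "config_hash",
    "field_to_csv",
    "field_to_json",
    "write_matrix_txt",
]

SCHEMA_VERSION = 1

MODEL_KEYS = ("lambda0", "g", "a", "c", "mu0", "Kg", "hg", "Ka", "ha")
RUN_KEYS = ("strategy", "signaling", "N")
COMMAND_KEYS = (
    "seed", "replicates", "n0", "m0", "event_cap", "delta", "quantity",
    "lambda0_grid", "c_grid", "Kg_set", "Ka_set", "hg_set", "ha_set",
    "Ka_values", "scenario", "N_report", "schema_version", "package_version",
)


class ConfigError(ValueError):
    """A configuration file contains an unknown or invalid entry."""


def load_config(path) -> dict:
    """Read a flat key-value config file (YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    return raw


def resolve_config(raw: dict):
    """Validate a raw config and fill defaults.

    Returns ``(params, strategy, signaling, N, extras, resolved)`` where
    ``resolved`` is the fully expanded dict written beside outputs.
    Unknown keys, invalid strategies, and non-positive rate constants are
    rejected with the offending key named.
    """
    known = set(MODEL_KEYS) | set(RUN_KEYS) | set(COMMAND_KEYS)
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")

    defaults = ModelParameters()
    kwargs = {}
    for key in MODEL_KEYS:
        if key in raw:
            val = raw[key]
            if key == "Ka" and isinstance(val, str):
                kwargs[key] = val
            else:
                try:
                    kwargs[key] = float(val)
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"config key {key!r}: not a number ({val!r})") from exc
        else:
            kwargs[key] = getattr(defaults, key)
            warnings.warn(
                f"config omits {key!r}; using package default {kwargs[key]!r}",
                stacklevel=2,
            )
    try:
        params = ModelParameters(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    try:
        strategy = Strategy(raw.get("strategy", "QS"))
    except ValueError as exc:
        raise ConfigError(f"invalid strategy {raw.get('strategy')!r}") from exc
    try:
        signaling = SignalingMode(raw.get("signaling", "producers_only"))
    except ValueError as exc:
        raise ConfigError(f"invalid signaling mode {raw.get('signaling')!r}") from exc
    N = int(raw.get("N", 100))
    if N < 2:
        raise ConfigError(f"N must be >= 2, got {N}")

    extras = {k: raw[k] for k in COMMAND_KEYS if k in raw}
    resolved = {key: getattr(params, key) for key in MODEL_KEYS}
    resolved.update(strategy=strategy.value, signaling=signaling.value, N=N)
    resolved.update(extras)
    resolved["schema_version"] = SCHEMA_VERSION
    return params, strategy, signaling, N, extras, resolved


def config_hash(resolved: dict) -> str:
    """Stable short hash of a resolved configuration."""
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_resolved_config(resolved: dict, out_dir) -> Path:
    out = Path(out_dir) / "resolved_config.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True, default_flow_style=False)
    return out


def field_to_csv(field: SolutionField, path) -> None:
    """Write a field as CSV with columns n, m, value (NaN -> empty)."""
    field.to_dataframe().to_csv(path, index=False)


def field_to_json(field: SolutionField, path) -> None:
    """Write a field as a JSON grid blob; undefined entries become null."""
    vals = [
        [None if not np.isfinite(v) else float(v) for v in row]
        for row in field.values
    ]
    meta = {k: v for k, v in field.meta.items() if isinstance(v, (str, int, float, bool, tuple, list))}
    with open(path, "w") as fh:
        json.dump({"quantity": field.quantity, "N": field.N, "meta": meta, "values": vals}, fh)


def write_matrix_txt(array: np.ndarray, path) -> None:
    """Plain-text matrix (rows = n, columns = m) for external heatmap tools."""
    np.savetxt(path, array, fmt="%.12g")
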