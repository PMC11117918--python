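"""Run configuration: one YAML/JSON file drives every pipeline stage.

The file mirrors the nested dataclasses: top-level keys ``phantom``,
``encoder``, ``train``, ``loss`` (nested under train), plus scalar keys of
:class:`~promptad.pipeline.BenchmarkConfig` such as ``alignment``,
``backbone_seed``, ``tau``, ``prompt_scope``, ``class_name``. Unknown keys
are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields, is_dataclass, replace
from pathlib import Path

import yaml

from .pipeline import BenchmarkConfig

__all__ = ["load_run_config", "dump_run_config"]


def _coerce(dc_obj, data: dict):
    """Rebuild a (frozen or not) dataclass with overrides from ``data``."""
    valid = {f.name: f for f in fields(dc_obj)}
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(f"unknown config keys for {type(dc_obj).__name__}: {sorted(unknown)}")
    updates = {}
    for key, val in data.items():
        cur = getattr(dc_obj, key)
        if is_dataclass(cur) and isinstance(val, dict):
            updates[key] = _coerce(cur, val)
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            updates[key] = tuple(val)
        else:
            updates[key] = val
    return replace(dc_obj, **updates) if _frozen(dc_obj) else _mutate(dc_obj, updates)


def _frozen(obj) -> bool:
    return obj.__dataclass_params__.frozen  # type: ignore[attr-defined]


def _mutate(obj, updates):
    for k, v in updates.items():
        setattr(obj, k, v)
    return obj


def load_run_config(path: str | Path | None) -> BenchmarkConfig:
    cfg = BenchmarkConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    return _coerce(cfg, data)


def _as_dict(obj):
    if is_dataclass(obj):
        return {f.name: _as_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_run_config(cfg: BenchmarkConfig) -> dict:
    """Config echo for run-metadata files (JSON-serializable)."""
    return _as_dict(cfg)
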