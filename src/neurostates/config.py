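"""Run configuration: defaults, YAML parsing, exhaustive validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS = {
    "fs": 400.0,
    "epoch_length": 0.5,
    "symbol_step": 0.5,
    "n_steps": 2400,
    "bands": {
        "delta": [0.5, 4.0],
        "gamma": [40.0, 60.0],
        "high_gamma": [60.0, 150.0],
    },
    "hmm": {"n_states": 3, "n_restarts": 10, "tol": 1e-6, "max_iter": 500},
    "granger": {"max_order_ms": 20.0, "Q": 0.05, "conditional": True},
    "cfc": {"low_band": [0.5, 4.0], "high_band": [40.0, 60.0], "weight": "amplitude"},
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated settings; all defaults match the reference analysis."""

    fs: float = 400.0
    epoch_length: float = 0.5
    symbol_step: float = 0.5
    n_steps: int = 2400
    bands: dict = field(default_factory=lambda: dict(DEFAULTS["bands"]))
    hmm: dict = field(default_factory=lambda: dict(DEFAULTS["hmm"]))
    granger: dict = field(default_factory=lambda: dict(DEFAULTS["granger"]))
    cfc: dict = field(default_factory=lambda: dict(DEFAULTS["cfc"]))
    seed: int = 0
    out_dir: str = "out"

    def to_dict(self) -> dict:
        return asdict(self)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(raw) -> RunConfig:
    """Build a RunConfig from YAML text, a path, a dict, or None.

    All schema violations are collected and reported together.
    """
    if raw is None:
        data = {}
    elif isinstance(raw, dict):
        data = raw
    else:
        candidate = Path(str(raw))
        is_file = "\n" not in str(raw) and str(raw) != "" and candidate.is_file()
        text = candidate.read_text() if is_file else str(raw)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(["config root must be a mapping"])

    known = set(DEFAULTS) | {"out_dir"}
    errors = [f"unknown field {k!r}" for k in data if k not in known]
    merged = _merge(DEFAULTS, {k: v for k, v in data.items() if k in known})

    fs = merged["fs"]
    if fs <= 0:
        errors.append(f"fs: must be positive, got {fs}")
    if merged["epoch_length"] <= 0:
        errors.append(f"epoch_length: must be positive, got {merged['epoch_length']}")
    if merged["symbol_step"] <= 0:
        errors.append(f"symbol_step: must be positive, got {merged['symbol_step']}")
    if merged["n_steps"] < 1:
        errors.append(f"n_steps: must be >= 1, got {merged['n_steps']}")
    nyquist = fs / 2 if fs > 0 else float("inf")
    for name, edges in merged["bands"].items():
        lo, hi = edges
        if not (0 <= lo < hi):
            errors.append(f"bands.{name}: need 0 <= lo < hi, got {edges}")
        if hi > nyquist:
            errors.append(
                f"bands.{name}: upper edge {hi} Hz above Nyquist {nyquist} Hz"
            )
    for bname in ("low_band", "high_band"):
        lo, hi = merged["cfc"][bname]
        if not (0 < lo < hi <= nyquist):
            errors.append(
                f"cfc.{bname}: ({lo}, {hi}) Hz invalid for Nyquist {nyquist} Hz"
            )
    if merged["hmm"]["n_states"] < 2:
        errors.append("hmm.n_states: must be >= 2")
    if merged["hmm"]["n_restarts"] < 1:
        errors.append("hmm.n_restarts: must be >= 1")
    if not (0 < merged["granger"]["Q"] < 1):
        errors.append("granger.Q: must lie in (0, 1)")
    if merged["granger"]["max_order_ms"] <= 0:
        errors.append("granger.max_order_ms: must be positive")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        fs=float(merged["fs"]),
        epoch_length=float(merged["epoch_length"]),
        symbol_step=float(merged["symbol_step"]),
        n_steps=int(merged["n_steps"]),
        bands={k: tuple(v) for k, v in merged["bands"].items()},
        hmm=dict(merged["hmm"]),
        granger=dict(merged["granger"]),
        cfc=dict(merged["cfc"]),
        seed=int(merged["seed"]),
        out_dir=str(data.get("out_dir", "out")),
    )
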