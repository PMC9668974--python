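"""Run configuration, validation, and output writers.

Configurations are plain YAML mappings validated against a small
schema: unknown keys are rejected by name, defaults are filled in, and
every run writes its fully-resolved configuration next to its outputs
so a result can always be regenerated from the directory alone.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import EventLog
from .stdp import StdpParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "write_outputs"]

EXPERIMENTS = (
    "simulate",
    "tongue-scan",
    "two-neuron",
    "network",
    "prc",
    "snic",
    "validate-resonance",
)
MODELS = ("qif", "winfree-tabulated", "wb", "ml")

#: experiments whose parameters feed the closed-form locking theory,
#: which is derived under p = d and tau_p <= tau_d
ANALYTIC_EXPERIMENTS = ("tongue-scan", "validate-resonance")


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


@dataclass
class RunConfig:
    experiment: str
    model: str = "qif"
    seed: int = 0
    outdir: str = "out"
    log_level: str = "INFO"
    t_max: float | None = None
    stdp: dict = field(
        default_factory=lambda: dict(p=0.001, d=0.001, tau_p=math.pi / 3, tau_d=math.pi)
    )
    params: dict = field(default_factory=dict)

    def stdp_params(self) -> StdpParams:
        return StdpParams(**self.stdp)


_TOP_KEYS = {"experiment", "model", "seed", "outdir", "log_level", "t_max", "stdp", "params"}
_STDP_KEYS = {"p", "d", "tau_p", "tau_d"}


def _validate(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)}; allowed: {sorted(_TOP_KEYS)}"
        )
    if "experiment" not in raw:
        raise ConfigError("missing required key 'experiment'")
    if raw["experiment"] not in EXPERIMENTS:
        raise ConfigError(
            f"key 'experiment': {raw['experiment']!r} not one of {EXPERIMENTS}"
        )
    if raw.get("model", "qif") not in MODELS:
        raise ConfigError(f"key 'model': {raw['model']!r} not one of {MODELS}")
    stdp = dict(RunConfig.__dataclass_fields__["stdp"].default_factory())
    user_stdp = raw.get("stdp", {})
    unknown = set(user_stdp) - _STDP_KEYS
    if unknown:
        raise ConfigError(f"key 'stdp': unknown subkey(s) {sorted(unknown)}")
    stdp.update(user_stdp)
    for k, v in stdp.items():
        if not isinstance(v, (int, float)) or v <= 0:
            raise ConfigError(f"key 'stdp.{k}': must be a positive number, got {v!r}")
    cfg = RunConfig(**{**raw, "stdp": stdp})
    if cfg.experiment in ANALYTIC_EXPERIMENTS and stdp["tau_p"] > stdp["tau_d"]:
        raise ConfigError(
            f"key 'stdp.tau_p': analytic locking theory ({cfg.experiment}) requires "
            f"tau_p <= tau_d, got tau_p={stdp['tau_p']} > tau_d={stdp['tau_d']}"
        )
    if cfg.t_max is not None and cfg.t_max <= 0:
        raise ConfigError(f"key 't_max': must be positive, got {cfg.t_max}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate(raw if raw is not None else {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a fully-resolved configuration (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    log: EventLog | None,
    report: dict | None,
    outdir: str | Path,
    *,
    config: RunConfig | None = None,
) -> dict:
    """Write the standard artifact set and return the checksum manifest.

    ``spikes.csv`` (t, neuron), ``weights.csv`` (t, i, j, w, long form of
    the sampled snapshots), ``final_W.json``, ``report.json``,
    ``resolved_config.yaml`` and ``manifest.json``.  Empty logs still
    produce headered CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if log is not None:
        p = outdir / "spikes.csv"
        pd.DataFrame({"t": log.spike_times, "neuron": log.spike_neurons}).to_csv(
            p, index=False
        )
        written.append(p)

        rows = []
        N = log.final_W.shape[0]
        for t, W in zip(log.weight_trace_times, log.weight_trace):
            for i in range(N):
                for j in range(N):
                    if i != j:
                        rows.append((t, i, j, W[i, j]))
        p = outdir / "weights.csv"
        pd.DataFrame(rows, columns=["t", "i", "j", "w"]).to_csv(p, index=False)
        written.append(p)

        p = outdir / "final_W.json"
        p.write_text(json.dumps(log.final_W.tolist(), indent=1))
        written.append(p)

    if report is not None:
        p = outdir / "report.json"
        p.write_text(json.dumps(_jsonable(report), indent=1))
        written.append(p)

    if config is not None:
        p = outdir / "resolved_config.yaml"
        save_config(config, p)
        written.append(p)

    manifest = {f.name: _sha256(f) for f in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return None if np.isnan(obj) else float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
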