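"""Configuration parsing, run manifests and text-based output.

Configs are flat YAML or JSON mappings mirroring :class:`SimConfig` (with
payoff parameters under ``v``/``c``/``a`` and the scheme under ``scheme``/
``memory_k``/``threshold``).  Unknown keys are rejected with their key
path.  All outputs are plain text (CSV / JSON); manifests record the
resolved config, seed, package version and content digests so a run can be
re-executed and verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abm import SimConfig
from .game import PayoffParams
from .reputation import SchemeSpec

__all__ = [
    "load_config",
    "config_to_dict",
    "dump_config",
    "RunManifest",
    "write_table",
    "read_table",
]

_PARAM_KEYS = ("v", "c", "a")
_SCHEME_KEYS = ("scheme", "memory_k", "threshold")
_SIM_KEYS = (
    "N", "N_F", "d", "u", "mu", "epsilon", "delta", "q_grid", "rounds",
    "seed", "q_continuous", "initial_reputation", "noise_mode",
    "reset_wealth_on_revision",
)


def _build(mapping: dict, source: str = "<config>") -> SimConfig:
    unknown = sorted(set(mapping) - set(_PARAM_KEYS) - set(_SCHEME_KEYS) - set(_SIM_KEYS))
    if unknown:
        raise ValueError(f"{source}: unknown configuration keys {unknown}")
    try:
        params = PayoffParams(
            v=float(mapping.get("v", 1.0)),
            c=float(mapping.get("c", 1.5)),
            a=float(mapping.get("a", 0.1)),
        )
    except ValueError as exc:
        raise ValueError(f"{source}: invalid payoff parameters: {exc}") from exc
    try:
        scheme = SchemeSpec(
            kind=mapping.get("scheme", "last_action"),
            memory_k=int(mapping.get("memory_k", 1)),
            threshold=mapping.get("threshold"),
        )
    except ValueError as exc:
        raise ValueError(f"{source}: invalid scheme: {exc}") from exc
    sim_kwargs = {}
    for key in _SIM_KEYS:
        if key in mapping:
            sim_kwargs[key] = mapping[key]
    if "q_grid" in sim_kwargs:
        sim_kwargs["q_grid"] = tuple(float(q) for q in sim_kwargs["q_grid"])
    try:
        return SimConfig(params=params, scheme=scheme, **sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: {exc}") from exc


def load_config(path: str | Path | None = None, **overrides) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML/JSON file, CLI-style keyword
    overrides, or both (overrides win).  Defaults fill every omitted key."""
    mapping: dict = {}
    source = "<flags>"
    if path is not None:
        path = Path(path)
        text = path.read_text()
        mapping = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: config must be a mapping")
        source = str(path)
    mapping.update({k: v for k, v in overrides.items() if v is not None})
    return _build(mapping, source=source)


def config_to_dict(config: SimConfig) -> dict:
    """Flat, JSON/YAML-serialisable form of a config (inverse of
    :func:`load_config`)."""
    out = {
        "v": config.params.v, "c": config.params.c, "a": config.params.a,
        "scheme": config.scheme.kind, "memory_k": config.scheme.memory_k,
        "threshold": config.scheme.threshold,
    }
    for key in _SIM_KEYS:
        val = getattr(config, key)
        if key == "q_grid":
            val = [float(q) for q in val]
        out[key] = val
    return out


def dump_config(config: SimConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _digest(path: Path) -> str:
    """SHA-256 over canonicalised text (universal newlines, UTF-8)."""
    text = path.read_text()
    return hashlib.sha256(text.replace("\r\n", "\n").encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record of one run: config, seed, version, timestamps
    and digests of the produced files."""

    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def start(cls, config: SimConfig) -> "RunManifest":
        return cls(
            config=config_to_dict(config),
            seed=config.seed,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, *output_paths: str | Path) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        for p in output_paths:
            p = Path(p)
            self.outputs[p.name] = _digest(p)
        return self

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV at full double precision (round-trips exactly)."""
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
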