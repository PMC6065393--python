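"""YAML run configuration, parameter profiles, and run manifests.

A run config names a parameter profile (the fitted study values are the
``"default"`` profile), a topology, a protocol and a mandatory seed, and
round-trips losslessly through YAML.  Unknown keys are rejected so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .growth import ModelParams
from .cycles import Perturbation, Protocol
from .networks import (
    Topology,
    barabasi_albert,
    fully_connected,
    isolated,
    read_edge_list,
    star,
    watts_strogatz,
)

__all__ = ["RunConfig", "PROFILES", "load_config", "save_config", "build_topology", "write_manifest"]

logger = logging.getLogger("metacoop")

#: named parameter profiles; "default" is the fitted study parameter set
PROFILES: dict[str, dict] = {
    "default": {
        "r": 0.5,
        "c": 0.07,
        "K": 90_000.0,
        "eps": 14.0,
        "k_m": 26.0,
        "t_grow": 22.0,
        "D": 650.0,
        "m": 0.6,
    },
}

_TOPOLOGY_KEYS = {
    "star": {"n_side"},
    "fully_connected": {"n"},
    "isolated": {"n"},
    "barabasi_albert": {"n", "m_attach", "seed"},
    "watts_strogatz": {"n", "k", "p", "seed"},
    "file": {"path"},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, round-trippable description of one run."""

    seed: int
    topology: dict
    protocol: Protocol
    profile: str | None = None
    output: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        p = self.protocol
        d = {
            "seed": self.seed,
            "profile": self.profile,
            "topology": dict(self.topology),
            "protocol": {
                "D": p.D,
                "m": p.m,
                "n_cycles": p.n_cycles,
                "extinction_cutoff": p.extinction_cutoff,
            },
            "params": asdict(p.params),
            "output": dict(self.output),
            "log_level": self.log_level,
        }
        if p.perturbation is not None:
            d["protocol"]["perturbation"] = asdict(p.perturbation)
        return d


def build_topology(spec: dict) -> Topology:
    """Instantiate a topology from its config mapping (``kind`` + options)."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind not in _TOPOLOGY_KEYS:
        raise ValueError(f"unknown topology kind {kind!r}; options: {sorted(_TOPOLOGY_KEYS)}")
    unknown = set(spec) - _TOPOLOGY_KEYS[kind]
    if unknown:
        raise ValueError(f"unknown topology keys for {kind!r}: {sorted(unknown)}")
    if kind == "star":
        return star(spec["n_side"])
    if kind == "fully_connected":
        return fully_connected(spec["n"])
    if kind == "isolated":
        return isolated(spec["n"])
    if kind == "barabasi_albert":
        return barabasi_albert(spec["n"], spec["m_attach"], seed=spec["seed"])
    if kind == "watts_strogatz":
        return watts_strogatz(spec["n"], spec["k"], spec["p"], seed=spec.get("seed"))
    return read_edge_list(spec["path"])


_TOP_KEYS = {"seed", "profile", "topology", "protocol", "params", "output", "log_level"}
_PROTOCOL_KEYS = {"D", "m", "n_cycles", "extinction_cutoff", "perturbation"}
_PARAM_KEYS = {"r", "c", "K", "eps", "k_m", "t_grow"}


def _config_from_dict(raw: dict) -> RunConfig:
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"seed", "topology"} - set(raw)
    if missing:
        raise ValueError(f"missing required config keys: {sorted(missing)}")

    profile = raw.get("profile")
    base = dict(PROFILES[profile]) if profile else {}
    if profile is not None and profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; options: {sorted(PROFILES)}")

    params_raw = dict(raw.get("params") or {})
    unknown = set(params_raw) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"unknown params keys: {sorted(unknown)}")
    param_vals = {k: base[k] for k in _PARAM_KEYS if k in base}
    param_vals.update(params_raw)
    if set(param_vals) != _PARAM_KEYS:
        raise ValueError(f"missing params keys: {sorted(_PARAM_KEYS - set(param_vals))}")
    params = ModelParams(**param_vals)

    proto_raw = dict(raw.get("protocol") or {})
    unknown = set(proto_raw) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    pert = proto_raw.pop("perturbation", None)
    for k in ("D", "m"):
        proto_raw.setdefault(k, base.get(k))
    if proto_raw["D"] is None or proto_raw["m"] is None:
        raise ValueError("protocol needs D and m (directly or via a profile)")
    protocol = Protocol(
        params=params,
        perturbation=None if pert is None else Perturbation(**pert),
        **proto_raw,
    )

    build_topology(raw["topology"])  # validate eagerly
    return RunConfig(
        seed=int(raw["seed"]),
        topology=dict(raw["topology"]),
        protocol=protocol,
        profile=profile,
        output=dict(raw.get("output") or {}),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"config {path} is empty or not a mapping")
    return _config_from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML such that ``load(save(x)) == x``."""
    d = config.to_dict()
    if d["profile"] is None:
        d.pop("profile")
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def write_manifest(path: str | Path, config: RunConfig, outputs: dict | None = None) -> dict:
    """Record everything needed to re-run a CLI invocation bit-for-bit."""
    import numpy, scipy, pandas
    import metacoop

    manifest = {
        "package": {"name": "metacoop", "version": metacoop.__version__},
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "config": config.to_dict(),
        "outputs": outputs or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
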