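"""The daily cycle: dilution → migration → growth, iterated over a protocol.

Each simulated day every well is diluted into fresh medium by the factor
``D``, a fraction ``m`` of the remaining cells migrates along the network,
and the cells then grow for ``t_grow`` hours.  Densities are recorded at the
end of growth, matching how optical density and cytometry were read out.
A one-cycle perturbation can substitute a harsher dilution ``D' = D·ΔD`` or
a reduced growth rate ``r' = r − Δr`` for a single cycle.

Because dilution and migration are both linear in the densities, their
relative order only affects which cycle a perturbation is book-kept against,
never the resulting state; the cycle is fixed as dilute-then-migrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import DEFAULT_ATOL, DEFAULT_PARAMS, DEFAULT_RTOL, ModelParams, NodeState, grow_many
from .networks import MigrationOperator, Topology, migration_matrix

__all__ = [
    "Perturbation",
    "Protocol",
    "Trajectory",
    "DEFAULT_EXTINCTION_CUTOFF",
    "run_cycle",
    "simulate",
    "standard_initial_state",
]

#: ≈ one cell in a 200 µL well — below this a strain is counted as extinct
DEFAULT_EXTINCTION_CUTOFF = 0.005

DILUTION_SHOCK = "dilution_shock"
GROWTH_SHOCK = "growth_shock"


@dataclass(frozen=True)
class Perturbation:
    """A one-cycle transient shock applied to all nodes simultaneously.

    ``kind="dilution_shock"`` multiplies that cycle's dilution factor by the
    magnitude ΔD (≥ 1); ``kind="growth_shock"`` subtracts the magnitude Δr
    (h⁻¹) from the growth rate for that cycle only.
    """

    cycle: int
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in (DILUTION_SHOCK, GROWTH_SHOCK):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.cycle < 0:
            raise ValueError("perturbation cycle must be >= 0")
        if self.kind == DILUTION_SHOCK and self.magnitude < 1:
            raise ValueError("dilution shock magnitude ΔD must be >= 1")
        if self.kind == GROWTH_SHOCK and self.magnitude < 0:
            raise ValueError("growth shock magnitude Δr must be >= 0")


@dataclass(frozen=True)
class Protocol:
    """Dilution/migration/growth schedule for a run."""

    D: float
    m: float
    params: ModelParams = DEFAULT_PARAMS
    n_cycles: int = 100
    perturbation: Perturbation | None = None
    extinction_cutoff: float = DEFAULT_EXTINCTION_CUTOFF
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("dilution factor D must be >= 1")
        if not 0 <= self.m <= 1:
            raise ValueError("migration rate m must be in [0, 1]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.extinction_cutoff < 0:
            raise ValueError("extinction cutoff must be non-negative")
        p = self.perturbation
        if p is not None and p.kind == GROWTH_SHOCK and p.magnitude > self.params.r:
            raise ValueError("growth shock Δr cannot exceed r")

    def replace(self, **changes) -> "Protocol":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def standard_initial_state(
    n: int, fraction: float = 0.1, total: float = 80_000.0
) -> np.ndarray:
    """Uniform dense start resembling an equilibrated overnight co-culture.

    The public-good Allee effect means dilute inocula can sit outside the
    survival basin even under benign protocols, so runs start from a
    saturated-culture-scale density by default.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if total < 0:
        raise ValueError("total density must be non-negative")
    return np.tile([fraction * total, (1 - fraction) * total], (n, 1)).astype(float)


def _as_state_array(states, n: int) -> np.ndarray:
    if isinstance(states, np.ndarray):
        arr = states.astype(float, copy=True)
    else:
        arr = np.array(
            [s.as_array() if isinstance(s, NodeState) else np.asarray(s, dtype=float) for s in states]
        )
    if arr.shape != (n, 2):
        raise ValueError(f"expected states of shape ({n}, 2), got {arr.shape}")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError("initial densities must be finite and non-negative")
    return arr


def run_cycle(
    states: np.ndarray,
    operator: MigrationOperator,
    protocol: Protocol,
    cycle_index: int,
) -> np.ndarray:
    """Advance all nodes through one dilution → migration → growth cycle.

    If ``cycle_index`` matches the protocol's perturbation, the shocked
    dilution factor or growth rate is substituted for this cycle only.
    After growth, any strain density below the extinction cutoff is set to
    exactly 0.
    """
    D_eff = protocol.D
    params = protocol.params
    p = protocol.perturbation
    if p is not None and p.cycle == cycle_index:
        if p.kind == DILUTION_SHOCK:
            D_eff = protocol.D * p.magnitude
        else:
            r_eff = params.r - p.magnitude
            if r_eff <= 0:
                # Δr == r: a cycle of pure dilution and migration, no growth
                dens = operator.M @ (states / D_eff)
                dens[dens < protocol.extinction_cutoff] = 0.0
                return dens
            params = params.replace(r=r_eff)
    dens = operator.M @ (states / D_eff)
    dens = grow_many(dens, params, rtol=protocol.rtol, atol=protocol.atol)
    dens[dens < protocol.extinction_cutoff] = 0.0
    return dens


@dataclass
class Trajectory:
    """Per-cycle, per-node record of a run, measured at the end of growth.

    ``states`` has shape ``(cycles_run, n_nodes, 2)``; ``cycles`` are the
    1-based cycle indices actually simulated.  If all nodes go extinct the
    run terminates early and ``all_extinct_cycle`` records when.
    """

    states: np.ndarray
    cycles: np.ndarray
    topology: Topology
    protocol: Protocol
    initial_states: np.ndarray
    all_extinct_cycle: int | None = None

    @property
    def final_states(self) -> np.ndarray:
        return self.states[-1]

    @property
    def extinct(self) -> np.ndarray:
        """Per-node extinction flags at the final recorded cycle."""
        return self.final_states.sum(axis=1) <= 0.0

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: cycle, node, role, Np, Nnp, total, fraction."""
        n_cyc, n_nodes, _ = self.states.shape
        cyc = np.repeat(self.cycles, n_nodes)
        node = np.tile(np.arange(n_nodes), n_cyc)
        n_p = self.states[:, :, 0].ravel()
        n_np = self.states[:, :, 1].ravel()
        total = n_p + n_np
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, n_p / np.where(total > 0, total, 1.0), np.nan)
        return pd.DataFrame(
            {
                "cycle": cyc,
                "node": node,
                "role": [self.topology.role(i) for i in node],
                "Np": n_p,
                "Nnp": n_np,
                "total": total,
                "fraction": frac,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def manifest(self) -> dict:
        """JSON-serialisable record of the full run configuration."""
        import metacoop

        p = self.protocol
        return {
            "package": {"name": "metacoop", "version": metacoop.__version__},
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
            "topology": {
                "n": self.topology.n,
                "edges": [list(e) for e in self.topology.edges],
                "labels": {str(k): v for k, v in self.topology.labels.items()},
            },
            "protocol": {
                "D": p.D,
                "m": p.m,
                "n_cycles": p.n_cycles,
                "extinction_cutoff": p.extinction_cutoff,
                "rtol": p.rtol,
                "atol": p.atol,
                "perturbation": None
                if p.perturbation is None
                else {
                    "cycle": p.perturbation.cycle,
                    "kind": p.perturbation.kind,
                    "magnitude": p.perturbation.magnitude,
                },
                "params": {
                    "r": p.params.r,
                    "c": p.params.c,
                    "K": p.params.K,
                    "eps": p.params.eps,
                    "k_m": p.params.k_m,
                    "t_grow": p.params.t_grow,
                },
            },
            "initial_states": self.initial_states.tolist(),
            "cycles_run": int(self.cycles[-1]) if len(self.cycles) else 0,
            "all_extinct_cycle": self.all_extinct_cycle,
        }

    def write_manifest(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.manifest(), indent=2) + "\n")


def simulate(
    topology: Topology,
    protocol: Protocol,
    initial_states: np.ndarray | Sequence[NodeState] | None = None,
    *,
    operator: MigrationOperator | None = None,
    record: bool = True,
) -> Trajectory:
    """Run ``protocol.n_cycles`` daily cycles on a topology.

    Deterministic: identical inputs give bitwise-identical trajectories.
    Terminates early (flagged) once every node is extinct, since extinction
    is absorbing.
    """
    if initial_states is None:
        initial_states = standard_initial_state(topology.n)
    dens = _as_state_array(initial_states, topology.n)
    init = dens.copy()
    if operator is None:
        operator = migration_matrix(topology, protocol.m)
    elif operator.n != topology.n:
        raise ValueError("operator dimension does not match topology")

    states: list[np.ndarray] = []
    cycles: list[int] = []
    all_extinct_cycle = None
    for t in range(protocol.n_cycles):
        dens = run_cycle(dens, operator, protocol, t)
        if record:
            states.append(dens.copy())
            cycles.append(t + 1)
        if not dens.any():
            all_extinct_cycle = t + 1
            break
    if not record or not states:
        states = [dens.copy()]
        cycles = [all_extinct_cycle or protocol.n_cycles]
    return Trajectory(
        states=np.array(states),
        cycles=np.array(cycles),
        topology=topology,
        protocol=protocol,
        initial_states=init,
        all_extinct_cycle=all_extinct_cycle,
    )
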