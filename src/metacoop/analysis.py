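"""Derived quantities and in-silico experiments on the metapopulation.

Equilibrium producer fractions, survival phase diagrams over (D, m),
bisection for the critical dilution factor (the tipping point), maximal
tolerated one-cycle shocks (resilience), basin-of-attraction recovery
thresholds, and a coarse constrained calibration of the growth constants.

All scans start, unless told otherwise, from the metapopulation equilibrated
at the benign reference protocol (D = 650 at the scanned migration rate),
mirroring how cultures were equilibrated before being challenged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cycles import (
    DEFAULT_EXTINCTION_CUTOFF,
    DILUTION_SHOCK,
    GROWTH_SHOCK,
    Perturbation,
    Protocol,
    Trajectory,
    run_cycle,
    standard_initial_state,
)
from .growth import DEFAULT_PARAMS, ModelParams
from .networks import Topology, migration_matrix

__all__ = [
    "ProducerFractions",
    "SteadyStateResult",
    "PhaseDiagram",
    "ResilienceResult",
    "RecoveryThreshold",
    "CalibrationCandidate",
    "producer_fraction",
    "steady_state",
    "survives",
    "phase_diagram",
    "critical_dilution",
    "max_shock",
    "recovery_threshold",
    "calibrate",
    "generations_per_cycle",
    "migration_per_generation",
    "REFERENCE_D",
]

#: benign reference dilution factor used to equilibrate before scans
REFERENCE_D = 650.0

#: fallback start when equilibration at the reference protocol fails
FALLBACK_INITIAL = (1000.0, 9000.0)


def generations_per_cycle(D: float) -> float:
    """Cell generations per daily cycle at equilibrium.

    At a steady cycle the population regrows exactly ``D``-fold after a
    ``D``-fold dilution, i.e. ``log2(D)`` doublings (≈ 9.3 at D = 650).
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    return math.log2(D)


def migration_per_generation(m: float, generations: float) -> float:
    """Per-generation migrant fraction implied by a per-cycle rate ``m``."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    return m / generations


# ---------------------------------------------------------------------------
# producer fractions


@dataclass(frozen=True)
class ProducerFractions:
    """Network-wide and per-node producer fractions over a cycle window."""

    cycles: np.ndarray
    overall: np.ndarray  # Σ Np / Σ (Np+Nnp) across nodes; NaN if empty
    per_node: np.ndarray  # shape (cycles, nodes); NaN for empty wells


def producer_fraction(trajectory: Trajectory, window: int | None = None) -> ProducerFractions:
    """Producer fractions of a trajectory, overall and per node.

    The overall fraction is total producers over total cells for the whole
    network.  ``window`` restricts to the final ``window`` recorded cycles.
    Fractions of empty wells (or an empty network) are NaN.
    """
    if trajectory.states.size == 0:
        raise ValueError("empty trajectory")
    states = trajectory.states
    cycles = trajectory.cycles
    if window is not None:
        if window < 1:
            raise ValueError("window must be >= 1")
        states = states[-window:]
        cycles = cycles[-window:]
    n_p = states[:, :, 0]
    tot = states.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_node = np.where(tot > 0, n_p / np.where(tot > 0, tot, 1.0), np.nan)
    net_tot = tot.sum(axis=1)
    overall = np.where(net_tot > 0, n_p.sum(axis=1) / np.where(net_tot > 0, net_tot, 1.0), np.nan)
    return ProducerFractions(cycles=cycles, overall=overall, per_node=per_node)


# ---------------------------------------------------------------------------
# steady states


CONVERGED = "converged"
OSCILLATORY = "oscillatory"
EXTINCT = "extinct"
MAX_CYCLES = "max_cycles"


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of iterating the cycle map to a stable state.

    For an oscillatory attractor, ``states`` is the minimum-total-density
    phase of the detected periodic orbit (the least resilient point, used
    as the reference for perturbation protocols) and ``period`` its length.
    """

    status: str  # converged | oscillatory | extinct | max_cycles
    states: np.ndarray
    period: int | None
    cycles_run: int
    min_phase_cycle: int | None = None

    @property
    def surviving(self) -> bool:
        return self.status in (CONVERGED, OSCILLATORY)


def _rel_change(a: np.ndarray, b: np.ndarray) -> float:
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1e-300)
    return float(np.max(np.abs(a - b))) / scale


def steady_state(
    topology: Topology,
    protocol: Protocol,
    initial_states: np.ndarray | None = None,
    *,
    tol: float = 1e-6,
    max_cycles: int = 2000,
    max_period: int = 32,
    step=None,
) -> SteadyStateResult:
    """Iterate daily cycles until a fixed point or periodic orbit is reached.

    Convergence means the maximum relative change of any node density over
    one cycle is below ``tol``.  A periodic orbit is recognised when the
    state recurs (within ``tol`` relative) at some period ≤ ``max_period``
    for two consecutive cycles; the minimum-density phase of the orbit is
    then returned.  Extinction of the whole network is reported distinctly,
    and so is failure to settle within ``max_cycles``.

    ``step`` optionally replaces the daily cycle map with a custom
    ``step(densities, cycle_index) -> densities`` (e.g. alternating
    protocols); the default is :func:`metacoop.run_cycle` under ``protocol``.
    """
    if initial_states is None:
        initial_states = standard_initial_state(topology.n)
    dens = np.asarray(initial_states, dtype=float).copy()
    op = migration_matrix(topology, protocol.m)
    if step is None:
        step = lambda d, t: run_cycle(d, op, protocol, t)  # noqa: E731
    history: list[np.ndarray] = [dens.copy()]
    keep = 2 * max_period + 2
    for t in range(max_cycles):
        dens = step(dens, t)
        if not dens.any():
            return SteadyStateResult(EXTINCT, dens.copy(), None, t + 1)
        history.append(dens.copy())
        if len(history) > keep:
            history.pop(0)
        if _rel_change(history[-1], history[-2]) < tol:
            return SteadyStateResult(CONVERGED, dens.copy(), None, t + 1)
        for p in range(2, max_period + 1):
            if len(history) < p + 2:
                break
            if (
                _rel_change(history[-1], history[-1 - p]) < tol
                and _rel_change(history[-2], history[-2 - p]) < tol
            ):
                orbit = history[-p:]
                totals = [s.sum() for s in orbit]
                k = int(np.argmin(totals))
                return SteadyStateResult(
                    OSCILLATORY,
                    orbit[k].copy(),
                    p,
                    t + 1,
                    min_phase_cycle=t + 1 - (p - 1) + k,
                )
    return SteadyStateResult(MAX_CYCLES, dens.copy(), None, max_cycles)


def survives(
    topology: Topology,
    protocol: Protocol,
    initial_states: np.ndarray | None = None,
    *,
    _converge_tol: float = 1e-10,
) -> bool:
    """True iff any node is above the extinction cutoff after ``n_cycles``.

    Exits early on all-node extinction (absorbing) or once the cycle map has
    converged to a fixed point well away from zero — a converged nonzero
    state survives all remaining cycles by definition.
    """
    if initial_states is None:
        initial_states = standard_initial_state(topology.n)
    dens = np.asarray(initial_states, dtype=float).copy()
    op = migration_matrix(topology, protocol.m)
    prev = dens.copy()
    for t in range(protocol.n_cycles):
        dens = run_cycle(dens, op, protocol, t)
        if not dens.any():
            return False
        if _rel_change(dens, prev) < _converge_tol:
            break
        prev = dens.copy()
    return bool((dens.sum(axis=1) > protocol.extinction_cutoff).any())


# ---------------------------------------------------------------------------
# phase diagram and critical dilution


@dataclass(frozen=True)
class PhaseDiagram:
    """Survival over a (dilution factor, migration rate) grid.

    ``survival[i, j]`` is survival at ``m_grid[i]``, ``D_grid[j]`` after
    ``n_cycles``.  ``monotonicity_violations`` lists (m, D_lo, D_hi) triples
    where the system survived the harsher dilution but not the milder one —
    reported, never silently dropped.
    """

    D_grid: np.ndarray
    m_grid: np.ndarray
    survival: np.ndarray
    n_cycles: int
    monotonicity_violations: tuple[tuple[float, float, float], ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"m": float(m), "D": float(D), "survives": bool(self.survival[i, j])}
            for i, m in enumerate(self.m_grid)
            for j, D in enumerate(self.D_grid)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _equilibrated_start(
    topology: Topology,
    m: float,
    params: ModelParams,
    cutoff: float,
    *,
    reference_D: float = REFERENCE_D,
) -> np.ndarray:
    """Standard scan start: equilibrium at the reference protocol.

    Falls back to a uniform (1000, 9000) cells/µL state when equilibration
    fails (extinction or non-convergence at the reference protocol).
    """
    ref = Protocol(D=reference_D, m=m, params=params, n_cycles=2000, extinction_cutoff=cutoff)
    ss = steady_state(topology, ref)
    if ss.surviving:
        return ss.states
    return np.tile(FALLBACK_INITIAL, (topology.n, 1)).astype(float)


def phase_diagram(
    topology: Topology,
    D_grid: Sequence[float],
    m_grid: Sequence[float],
    params: ModelParams = DEFAULT_PARAMS,
    *,
    n_cycles: int = 1000,
    extinction_cutoff: float | None = None,
) -> PhaseDiagram:
    """Survival map over a grid of dilution factors and migration rates.

    Each grid point is evaluated independently from the equilibrated
    standard start at that migration rate.  The m = 0 row coincides exactly
    with isolated-node behaviour because the dispersal operator is then the
    identity.
    """
    D_grid = np.asarray(sorted(D_grid), dtype=float)
    m_grid = np.asarray(sorted(m_grid), dtype=float)
    cutoff = DEFAULT_EXTINCTION_CUTOFF if extinction_cutoff is None else extinction_cutoff
    surv = np.zeros((len(m_grid), len(D_grid)), dtype=bool)
    violations = []
    for i, m in enumerate(m_grid):
        init = _equilibrated_start(topology, float(m), params, cutoff)
        for j, D in enumerate(D_grid):
            proto = Protocol(
                D=float(D), m=float(m), params=params, n_cycles=n_cycles, extinction_cutoff=cutoff
            )
            surv[i, j] = survives(topology, proto, init)
        for j in range(len(D_grid) - 1):
            if not surv[i, j] and surv[i, j + 1 :].any():
                k = j + 1 + int(np.argmax(surv[i, j + 1 :]))
                violations.append((float(m), float(D_grid[j]), float(D_grid[k])))
    return PhaseDiagram(
        D_grid=D_grid,
        m_grid=m_grid,
        survival=surv,
        n_cycles=n_cycles,
        monotonicity_violations=tuple(violations),
    )


class BracketError(ValueError):
    """The supplied bracket does not straddle the survival/collapse boundary."""


def critical_dilution(
    topology: Topology,
    m: float,
    params: ModelParams = DEFAULT_PARAMS,
    *,
    bracket: tuple[float, float] = (400.0, 2000.0),
    tol: float = 1e-3,
    n_cycles: int = 1000,
    extinction_cutoff: float | None = None,
    initial_states: np.ndarray | None = None,
) -> float:
    """Critical dilution factor D* (tipping point) by bisection.

    Survival over ``n_cycles`` from the equilibrated standard start must
    hold at the lower bracket endpoint and fail at the upper one; the
    boundary is then bisected to relative tolerance ``tol`` and the final
    bracket midpoint returned.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 1 <= lo < hi:
        raise ValueError("need 1 <= bracket[0] < bracket[1]")
    cutoff = DEFAULT_EXTINCTION_CUTOFF if extinction_cutoff is None else extinction_cutoff
    if initial_states is None:
        initial_states = _equilibrated_start(topology, m, params, cutoff)

    def ok(D: float) -> bool:
        proto = Protocol(D=D, m=m, params=params, n_cycles=n_cycles, extinction_cutoff=cutoff)
        return survives(topology, proto, initial_states)

    if not ok(lo):
        raise BracketError(f"population collapses already at D={lo}")
    if ok(hi):
        raise BracketError(f"population still survives at D={hi}")
    while hi - lo > tol * 0.5 * (hi + lo):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# resilience


@dataclass(frozen=True)
class ResilienceResult:
    """Maximal one-cycle shock a metapopulation can absorb and recover from."""

    baseline_D: float
    kind: str  # dilution_shock | growth_shock
    max_magnitude: float  # ΔD^max (≥ 1) or Δr^max (≥ 0, h⁻¹)
    tol: float
    bracket: tuple[float, float]
    steady_state: SteadyStateResult = field(repr=False, compare=False, default=None)
    capped: bool = False  # True if even the largest probed shock was absorbed


def _recovers(
    topology: Topology,
    protocol: Protocol,
    eq_states: np.ndarray,
    eq_total: float,
    *,
    relax_cycles: int,
    recovery_frac: float,
    start_states: np.ndarray | None = None,
) -> bool:
    """Shock (if the protocol carries one) then relax; True on recovery.

    Recovery means the all-node total density returns within
    ``recovery_frac`` of the pre-shock steady-state total before the
    relaxation horizon runs out.
    """
    op = migration_matrix(topology, protocol.m)
    dens = (eq_states if start_states is None else start_states).copy()
    for t in range(relax_cycles):
        dens = run_cycle(dens, op, protocol, t)
        if not dens.any():
            return False
        if abs(dens.sum() - eq_total) <= recovery_frac * eq_total:
            return True
    return False


def max_shock(
    topology: Topology,
    protocol: Protocol,
    kind: str,
    *,
    bracket: tuple[float, float] | None = None,
    tol: float = 0.01,
    relax_cycles: int = 500,
    recovery_frac: float = 0.05,
    steady_kwargs: dict | None = None,
) -> ResilienceResult:
    """Largest one-cycle shock survivable at the baseline protocol.

    The metapopulation is first brought to its stable state (minimum-density
    phase if oscillatory), shocked for a single cycle — an extra dilution
    factor ΔD or a growth-rate reduction Δr — and relaxed for up to
    ``relax_cycles``.  The recovery/extinction boundary is bisected to
    relative tolerance ``tol``; classification is assumed monotone in the
    magnitude and is verified at the bracket endpoints.
    """
    if kind not in (DILUTION_SHOCK, GROWTH_SHOCK):
        raise ValueError(f"unknown shock kind {kind!r}")
    ss = steady_state(topology, protocol, **(steady_kwargs or {}))
    if not ss.surviving:
        raise ValueError(f"baseline protocol is not survivable (status={ss.status})")
    eq = ss.states
    eq_total = float(eq.sum())

    def rec(mag: float) -> bool:
        shocked = protocol.replace(perturbation=Perturbation(cycle=0, kind=kind, magnitude=mag))
        return _recovers(
            topology, shocked, eq, eq_total, relax_cycles=relax_cycles, recovery_frac=recovery_frac
        )

    if kind == DILUTION_SHOCK:
        lo = 1.0 if bracket is None else float(bracket[0])
        if not rec(lo):
            raise BracketError(f"no recovery even at ΔD={lo}")
        if bracket is None:
            hi = 4.0
            while rec(hi):
                lo = hi
                hi *= 4.0
                if hi > 1e6:
                    return ResilienceResult(protocol.D, kind, hi, tol, (lo, hi), ss, capped=True)
        else:
            hi = float(bracket[1])
            if rec(hi):
                return ResilienceResult(protocol.D, kind, hi, tol, (lo, hi), ss, capped=True)
        while hi - lo > tol * lo:
            mid = math.sqrt(lo * hi)  # geometric: ΔD spans decades
            if rec(mid):
                lo = mid
            else:
                hi = mid
    else:
        r = protocol.params.r
        lo = 0.0 if bracket is None else float(bracket[0])
        hi = r if bracket is None else float(bracket[1])
        if not rec(lo):
            raise BracketError(f"no recovery even at Δr={lo}")
        if rec(hi):
            return ResilienceResult(protocol.D, kind, hi, tol, (lo, hi), ss, capped=True)
        while hi - lo > tol * r:
            mid = 0.5 * (lo + hi)
            if rec(mid):
                lo = mid
            else:
                hi = mid
    return ResilienceResult(protocol.D, kind, 0.5 * (lo + hi), tol, (lo, hi), ss)


@dataclass(frozen=True)
class RecoveryThreshold:
    """Basin boundary along the uniform-scaling direction."""

    scaling: float  # minimal fraction s of the equilibrium state
    density: float  # s × mean per-node equilibrium total (cells/µL)
    tol: float
    steady_state: SteadyStateResult = field(repr=False, compare=False, default=None)


def recovery_threshold(
    topology: Topology,
    protocol: Protocol,
    *,
    tol: float = 0.01,
    relax_cycles: int = 500,
    recovery_frac: float = 0.05,
    s_min: float = 1e-6,
) -> RecoveryThreshold:
    """Minimum uniform density (fraction of equilibrium) that still recovers.

    Bisects the scalar ``s ∈ (0, 1]`` multiplying the equilibrium state of
    every node; returns the boundary both as the scaling and as
    ``s × mean per-node equilibrium density`` in cells/µL (the dashed
    unstable-branch line of a bifurcation diagram).
    """
    ss = steady_state(topology, protocol)
    if not ss.surviving:
        raise ValueError(f"baseline protocol is not survivable (status={ss.status})")
    eq = ss.states
    eq_total = float(eq.sum())

    def rec(s: float) -> bool:
        return _recovers(
            topology,
            protocol,
            eq,
            eq_total,
            relax_cycles=relax_cycles,
            recovery_frac=recovery_frac,
            start_states=s * eq,
        )

    if not rec(1.0):
        raise BracketError("equilibrium state itself does not re-equilibrate")
    lo, hi = s_min, 1.0
    if rec(lo):  # no Allee threshold along this direction
        boundary = lo
    else:
        while hi - lo > tol * hi:
            mid = math.sqrt(lo * hi)
            if rec(mid):
                hi = mid
            else:
                lo = mid
        boundary = 0.5 * (lo + hi)
    mean_eq = eq_total / topology.n
    return RecoveryThreshold(scaling=boundary, density=boundary * mean_eq, tol=tol, steady_state=ss)


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationCandidate:
    params: ModelParams
    predictions: dict
    score: float


def calibrate(
    targets: dict,
    *,
    base: ModelParams = DEFAULT_PARAMS,
    c_grid: Sequence[float] = (0.03, 0.05, 0.07, 0.09),
    eps_ratio_grid: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    t_grow_grid: Sequence[float] = (19.0, 20.0, 21.0, 22.0),
    D: float = REFERENCE_D,
    critical_kwargs: dict | None = None,
    top: int = 5,
) -> list[CalibrationCandidate]:
    """Coarse grid reconstruction of the manual parameter fit.

    Scans cost ``c``, private-benefit ratio ``eps/k_m`` and growth duration
    within their biological constraint box, scoring each candidate by the
    summed squared relative error of its predictions against the supplied
    summary targets.  Recognised target keys: ``equilibrium_fraction`` (the
    isolated-node equilibrium producer fraction at dilution ``D``) and
    ``critical_dilution`` (the isolated-node tipping point).  This is a
    convenience reconstruction of a manual fit, not an inference method.
    """
    known = {"equilibrium_fraction", "critical_dilution"}
    unknown = set(targets) - known
    if unknown:
        raise ValueError(f"unknown calibration targets: {sorted(unknown)}")
    if not targets:
        raise ValueError("at least one target is required")
    from .networks import isolated

    topo = isolated(1)
    out = []
    for c, ratio, tg in product(c_grid, eps_ratio_grid, t_grow_grid):
        params = base.replace(c=c, eps=ratio * base.k_m, t_grow=tg)
        preds: dict = {}
        score = 0.0
        ss = steady_state(topo, Protocol(D=D, m=0.0, params=params, n_cycles=2000))
        if ss.surviving:
            s = ss.states
            preds["equilibrium_fraction"] = float(s[:, 0].sum() / s.sum())
        else:
            preds["equilibrium_fraction"] = float("nan")
        if "critical_dilution" in targets:
            try:
                preds["critical_dilution"] = critical_dilution(
                    topo, 0.0, params, **(critical_kwargs or {"tol": 0.02, "n_cycles": 500})
                )
            except BracketError:
                preds["critical_dilution"] = float("nan")
        for key, want in targets.items():
            got = preds.get(key, float("nan"))
            score += ((got - want) / want) ** 2 if math.isfinite(got) else 1e6
        out.append(CalibrationCandidate(params=params, predictions=preds, score=score))
    out.sort(key=lambda cand: cand.score)
    return out[:top]
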