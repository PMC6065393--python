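"""Network topologies and the degree-dependent asymmetric dispersal operator.

Every node exports the same fraction ``m`` of its cells per cycle,
distributed evenly among its neighbours — as for organisms with a
specialised dispersal stage, the exported fraction does not depend on how
many neighbours a node has.  On a heterogeneous graph this makes migration
asymmetric: the flux along an edge is ``m/deg(source)`` of the source, so
low-degree nodes lose more per link and net migration flows toward hubs.
In a star, each side node sends ``m`` of its cells to the centre while the
centre returns only ``m/n_side`` to each side node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "MigrationOperator",
    "star",
    "fully_connected",
    "isolated",
    "barabasi_albert",
    "watts_strogatz",
    "migration_matrix",
    "migrate",
    "degree_variance",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True, eq=False)
class Topology:
    """Undirected simple graph with optional node roles.

    ``edges`` is a canonical tuple of ``(i, j)`` pairs with ``i < j``; no
    self-loops or multi-edges.  ``labels`` maps node index to a role string
    such as ``"center"`` or ``"side"`` (used in tidy exports).
    """

    n: int
    edges: tuple[tuple[int, int], ...]
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("topology needs at least one node")
        seen = set()
        canon = []
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i}")
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i}, {j}) out of range for n={self.n}")
            e = (min(i, j), max(i, j))
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
            canon.append(e)
        object.__setattr__(self, "edges", tuple(sorted(canon)))

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def role(self, node: int) -> str:
        return self.labels.get(node, "node")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, labels: dict[int, str] | None = None) -> "Topology":
        nodes = sorted(g.nodes())
        if nodes != list(range(len(nodes))):
            mapping = {v: k for k, v in enumerate(nodes)}
            g = nx.relabel_nodes(g, mapping)
        return cls(n=g.number_of_nodes(), edges=tuple(g.edges()), labels=labels or {})

    def __eq__(self, other) -> bool:  # labels participate; edges are canonical
        if not isinstance(other, Topology):
            return NotImplemented
        return (self.n, self.edges, self.labels) == (other.n, other.edges, other.labels)


@dataclass(frozen=True, eq=False)
class MigrationOperator:
    """Column-stochastic per-cycle dispersal matrix.

    Column ``j`` describes where the cells of source node ``j`` end up:
    a fraction ``1 - m`` stays (1 for isolated nodes) and ``m/deg(j)``
    crosses each incident edge.  Column-stochasticity is exact cell-number
    conservation.
    """

    M: np.ndarray
    m: float

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        object.__setattr__(self, "M", M)

    @property
    def n(self) -> int:
        return self.M.shape[0]


# ---------------------------------------------------------------------------
# generators


def star(n_side: int) -> Topology:
    """Star of one centre (node 0) connected to ``n_side`` side nodes."""
    if n_side < 1:
        raise ValueError("a star needs at least one side node")
    edges = tuple((0, i) for i in range(1, n_side + 1))
    labels = {0: "center", **{i: "side" for i in range(1, n_side + 1)}}
    return Topology(n=n_side + 1, edges=edges, labels=labels)


def fully_connected(n: int) -> Topology:
    """Complete graph on ``n`` nodes (symmetric migration control)."""
    if n < 1:
        raise ValueError("need at least one node")
    edges = tuple((i, j) for i in range(n) for j in range(i + 1, n))
    return Topology(n=n, edges=edges)


def isolated(n: int) -> Topology:
    """``n`` nodes with no edges (independent wells)."""
    if n < 1:
        raise ValueError("need at least one node")
    return Topology(n=n, edges=())


def barabasi_albert(n: int = 100, m_attach: int = 2, seed: int | None = None) -> Topology:
    """Barabási–Albert preferential-attachment scale-free graph."""
    if seed is None:
        raise ValueError("seed is required for reproducible generation")
    if not 1 <= m_attach < n:
        raise ValueError("need 1 <= m_attach < n")
    return Topology.from_networkx(nx.barabasi_albert_graph(n, m_attach, seed=seed))


def watts_strogatz(n: int = 100, k: int = 4, p: float = 0.1, seed: int | None = None) -> Topology:
    """Watts–Strogatz small-world graph (ring lattice rewired with prob. p)."""
    if seed is None and p > 0:
        raise ValueError("seed is required for reproducible generation")
    if k % 2 != 0:
        raise ValueError("k must be even for a ring lattice")
    if not 0 <= p <= 1:
        raise ValueError("rewiring probability p must be in [0, 1]")
    return Topology.from_networkx(nx.watts_strogatz_graph(n, k, p, seed=seed))


# ---------------------------------------------------------------------------
# migration


def migration_matrix(topology: Topology, m: float) -> MigrationOperator:
    """Build the dispersal operator for per-cycle migrant fraction ``m``."""
    if not 0 <= m <= 1:
        raise ValueError("migration rate m must be in [0, 1]")
    n = topology.n
    deg = topology.degrees
    M = np.zeros((n, n))
    for j in range(n):
        M[j, j] = 1.0 - m if deg[j] >= 1 else 1.0
    for i, j in topology.edges:
        M[i, j] = m / deg[j]
        M[j, i] = m / deg[i]
    return MigrationOperator(M=M, m=m)


def migrate(densities: np.ndarray, op: MigrationOperator) -> np.ndarray:
    """Apply one round of simultaneous migration to per-node densities.

    ``densities`` may be a vector of shape ``(n,)`` or per-strain columns
    ``(n, k)``; the operator acts identically and independently on each
    column, conserving each column's total exactly (up to round-off).
    """
    dens = np.asarray(densities, dtype=float)
    if dens.shape[0] != op.n:
        raise ValueError(f"expected {op.n} nodes, got {dens.shape[0]}")
    if (dens < 0).any():
        raise ValueError("densities must be non-negative")
    return op.M @ dens


def degree_variance(topology: Topology) -> float:
    """Population variance of the degree sequence (graph heterogeneity)."""
    return float(np.var(topology.degrees))


# ---------------------------------------------------------------------------
# edge-list text I/O


def write_edge_list(topology: Topology, path: str | Path) -> None:
    """Write a two-column 0-based integer edge list (isolated nodes kept via header)."""
    lines = [f"# nodes: {topology.n}"]
    lines += [f"{i} {j}" for i, j in topology.edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> Topology:
    """Read a two-column edge list; ``# nodes: n`` header preserves isolated nodes."""
    n_declared = None
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "nodes:" in line:
                n_declared = int(line.split("nodes:")[1])
            continue
        i, j = line.split()[:2]
        edges.append((int(i), int(j)))
    n = n_declared if n_declared is not None else (max(max(e) for e in edges) + 1 if edges else 1)
    return Topology(n=n, edges=tuple(edges))
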