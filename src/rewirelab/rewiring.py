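"""Degree-preserving targeted rewiring.

Three algorithms manipulate one structural property each while leaving every
node's degree untouched:

* ``assortativity`` — pick two disjoint edges and re-pair their endpoints so
  the two higher-degree nodes are joined and the two lower-degree nodes are
  joined, whenever that strictly raises the sum of endpoint-degree products
  (and hence the degree assortativity r).
* ``clustering`` — pick a 5-node simple path p-u-A-v-q centred on a random
  node A, break the end edges (p,u) and (v,q), close the triangle (u,v) and
  add (p,q); committed only when the mean local clustering strictly rises.
* ``geodesic`` — pick a node pair with probability proportional to its
  distance, shortcut it directly, and re-join one degree-weighted neighbour
  of each endpoint; committed only when the mean geodesic strictly falls.

Every committed swap preserves simplicity and connectivity; failed proposals
are reverted.  A shared controller runs attempts in windows, snapshots the
full property vector at window boundaries, and stops once fewer than
``1 - convergence`` of a window's proposals succeed or a maximum attempt
budget is exhausted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from pathlib import Path
from typing import Literal, Optional

import networkx as nx
import numpy as np

from .metrics import PROPERTY_COLUMNS, PropertyVector, _distance_matrix, measure_all

__all__ = [
    "Algorithm",
    "AttemptOutcome",
    "RewiringConfig",
    "Trajectory",
    "attempt_assortativity_swap",
    "attempt_clustering_rewire",
    "attempt_geodesic_rewire",
    "evaluate_assortativity_swap",
    "evaluate_clustering_rewire",
    "evaluate_geodesic_rewire",
    "run_rewiring",
]

Algorithm = Literal["assortativity", "clustering", "geodesic"]
ALGORITHMS: tuple[Algorithm, ...] = ("assortativity", "clustering", "geodesic")

Reason = Literal[
    "committed",
    "already-optimal",
    "duplicate-edge",
    "would-disconnect",
    "no-valid-path",
    "no-improvement",
    "degenerate-selection",
]


@dataclass(frozen=True)
class AttemptOutcome:
    """Result of one proposal: whether it was committed, and if not, why.

    Geodesic attempts that commit also carry the refreshed all-pairs
    distance table, so the caller never recomputes it.
    """

    committed: bool
    reason: Reason
    distances: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.committed != (self.reason == "committed"):
            raise ValueError("committed flag must match reason")


@dataclass(frozen=True)
class RewiringConfig:
    """Controller settings for one rewiring run.

    ``window_size`` is the number of attempts between property snapshots;
    ``convergence`` is the window failure rate that stops the run (0.9 means
    a window with under 10% successes terminates); ``max_attempts`` caps the
    total number of proposals.
    """

    algorithm: Algorithm
    window_size: int
    convergence: float = 0.9
    max_attempts: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.window_size < 1:
            raise ValueError("window_size must be a positive integer")
        if not (0.0 < self.convergence < 1.0):
            raise ValueError("convergence must lie strictly between 0 and 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be a positive integer")

    @classmethod
    def default_for(cls, algorithm: Algorithm, m: int, seed: int = 0) -> "RewiringConfig":
        """Standard controller settings as a function of the edge count M.

        Windows of 20% of M and an attempt cap of 10·M for assortativity and
        clustering; the geodesic algorithm pays two all-pairs shortest-path
        computations per attempt, so it uses windows of 10% of M and a cap of
        M to keep its cost bounded.
        """
        if algorithm == "geodesic":
            return cls(algorithm, window_size=ceil(0.1 * m), max_attempts=m, seed=seed)
        return cls(algorithm, window_size=ceil(0.2 * m), max_attempts=10 * m, seed=seed)


@dataclass
class Trajectory:
    """Ordered property snapshots over one rewiring run.

    Each snapshot is ``(attempt_index, cumulative_successes, PropertyVector)``;
    the first is always at attempt 0 and a terminal snapshot is always
    recorded, even when the run stops mid-window.
    """

    sequence_name: str
    network_replicate: int
    run_replicate: int
    algorithm: Algorithm
    config: RewiringConfig
    snapshots: list[tuple[int, int, PropertyVector]] = field(default_factory=list)

    HEADER = "# rewirelab trajectory v1"
    META_COLUMNS = ("sequence", "network_replicate", "run_replicate", "algorithm",
                    "window_size", "convergence", "max_attempts", "seed")

    def rows(self):
        meta = (self.sequence_name, self.network_replicate, self.run_replicate,
                self.algorithm, self.config.window_size, self.config.convergence,
                self.config.max_attempts, self.config.seed)
        for attempt, successes, pv in self.snapshots:
            yield list(meta) + [attempt, successes] + pv.to_row()

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            fh.write(self.HEADER + "\n")
            writer = csv.writer(fh)
            writer.writerow(list(self.META_COLUMNS) + ["attempt", "successes"] + list(PROPERTY_COLUMNS))
            writer.writerows(self.rows())


def _connected_after(net: nx.Graph, probe) -> bool:
    # single traversal from an affected node; connected iff it reaches all nodes
    return len(nx.node_connected_component(net, probe)) == net.number_of_nodes()


# ---------------------------------------------------------------------------
# assortativity
# ---------------------------------------------------------------------------

def evaluate_assortativity_swap(net: nx.Graph, edge1, edge2) -> AttemptOutcome:
    """Assess and (if favourable) apply the re-pairing of two disjoint edges.

    The proposal joins the two highest-degree and the two lowest-degree of
    the four endpoints.  Commits only when that strictly raises the sum of
    endpoint-degree products, introduces no duplicate edge, and keeps the
    graph connected; otherwise the graph is left unchanged.
    """
    a, b = edge1
    c, d = edge2
    nodes = {a, b, c, d}
    if len(nodes) < 4:
        return AttemptOutcome(False, "degenerate-selection")
    deg = {v: net.degree(v) for v in nodes}
    current = deg[a] * deg[b] + deg[c] * deg[d]
    lo1, lo2, hi1, hi2 = sorted(nodes, key=lambda v: (deg[v], v))
    proposed = deg[hi1] * deg[hi2] + deg[lo1] * deg[lo2]
    if proposed <= current:
        return AttemptOutcome(False, "already-optimal")
    if net.has_edge(hi1, hi2) or net.has_edge(lo1, lo2):
        return AttemptOutcome(False, "duplicate-edge")
    net.remove_edge(a, b)
    net.remove_edge(c, d)
    net.add_edge(hi1, hi2)
    net.add_edge(lo1, lo2)
    if not _connected_after(net, a):
        net.remove_edge(hi1, hi2)
        net.remove_edge(lo1, lo2)
        net.add_edge(a, b)
        net.add_edge(c, d)
        return AttemptOutcome(False, "would-disconnect")
    return AttemptOutcome(True, "committed")


def attempt_assortativity_swap(net: nx.Graph, rng: np.random.Generator) -> AttemptOutcome:
    """One assortativity proposal: two edges chosen uniformly without replacement."""
    edges = list(net.edges())
    if len(edges) < 2:
        raise ValueError("assortativity rewiring needs at least two edges")
    i, j = rng.choice(len(edges), size=2, replace=False)
    return evaluate_assortativity_swap(net, edges[i], edges[j])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _clustering_sum(net: nx.Graph, nodes) -> Fraction:
    # exact rational sum of local coefficients C_i = 2 T_i / (d_i (d_i - 1)),
    # so that zero-change proposals are never committed through float noise
    total = Fraction(0)
    for v, t in nx.triangles(net, nodes).items():
        d = net.degree(v)
        if d >= 2:
            total += Fraction(2 * t, d * (d - 1))
    return total


def evaluate_clustering_rewire(net: nx.Graph, p, u, a, v, q) -> AttemptOutcome:
    """Assess the triangle-closing rewire on the 5-node path p-u-a-v-q.

    Breaks (p,u) and (v,q), adds (u,v) — closing the triangle u-a-v — and
    (p,q).  Commits only if neither added edge already exists, the graph
    stays connected, and the mean local clustering strictly increases (the
    removed edges may destroy other triangles).
    """
    nodes = (p, u, a, v, q)
    if len(set(nodes)) < 5:
        raise ValueError("the five path nodes must be distinct")
    for x, y in ((p, u), (u, a), (a, v), (v, q)):
        if not net.has_edge(x, y):
            raise ValueError("p-u-a-v-q is not a path in the graph")
    if net.has_edge(u, v) or net.has_edge(p, q):
        return AttemptOutcome(False, "duplicate-edge")
    # nodes whose local coefficient can change: path ends/centres and any
    # common neighbour of a changed edge's endpoints, all within this set
    affected = {p, u, v, q}
    for x in (p, u, v, q):
        affected.update(net.neighbors(x))
    before = _clustering_sum(net, affected)
    net.remove_edge(p, u)
    net.remove_edge(v, q)
    net.add_edge(u, v)
    net.add_edge(p, q)

    def revert():
        net.remove_edge(u, v)
        net.remove_edge(p, q)
        net.add_edge(p, u)
        net.add_edge(v, q)

    if not _connected_after(net, u):
        revert()
        return AttemptOutcome(False, "would-disconnect")
    if _clustering_sum(net, affected) <= before:
        revert()
        return AttemptOutcome(False, "no-improvement")
    return AttemptOutcome(True, "committed")


def attempt_clustering_rewire(net: nx.Graph, rng: np.random.Generator) -> AttemptOutcome:
    """One clustering proposal: random centre, incident edge pair, and extensions."""
    candidates = [x for x in sorted(net.nodes()) if net.degree(x) >= 2]
    if not candidates:
        return AttemptOutcome(False, "no-valid-path")
    a = candidates[rng.integers(len(candidates))]
    nbrs = list(net.neighbors(a))
    i, j = rng.choice(len(nbrs), size=2, replace=False)
    u, v = nbrs[i], nbrs[j]
    p_choices = [x for x in net.neighbors(u) if x != a and x != v]
    if not p_choices:
        return AttemptOutcome(False, "no-valid-path")
    p = p_choices[rng.integers(len(p_choices))]
    q_choices = [x for x in net.neighbors(v) if x != a and x != u and x != p]
    if not q_choices:
        return AttemptOutcome(False, "no-valid-path")
    q = q_choices[rng.integers(len(q_choices))]
    return evaluate_clustering_rewire(net, p, u, a, v, q)


# ---------------------------------------------------------------------------
# geodesic
# ---------------------------------------------------------------------------

def evaluate_geodesic_rewire(net: nx.Graph, a, b, c, d,
                             distances: np.ndarray) -> AttemptOutcome:
    """Assess the shortcut rewire joining (a,b) and (c,d) for neighbours c of a, d of b.

    Removes (a,c) and (b,d); commits only when the resulting graph is
    connected and its mean geodesic is strictly smaller, otherwise reverts.
    On commit the outcome carries the recomputed distance table.
    """
    if len({a, b, c, d}) < 4:
        return AttemptOutcome(False, "degenerate-selection")
    if net.has_edge(a, b) or net.has_edge(c, d):
        return AttemptOutcome(False, "duplicate-edge")
    if not net.has_edge(a, c) or not net.has_edge(b, d):
        raise ValueError("c must neighbour a and d must neighbour b")
    net.remove_edge(a, c)
    net.remove_edge(b, d)
    net.add_edge(a, b)
    net.add_edge(c, d)

    def revert():
        net.remove_edge(a, b)
        net.remove_edge(c, d)
        net.add_edge(a, c)
        net.add_edge(b, d)

    if not _connected_after(net, a):
        revert()
        return AttemptOutcome(False, "would-disconnect")
    new_distances = _distance_matrix(net)
    if new_distances.sum() >= distances.sum():
        revert()
        return AttemptOutcome(False, "no-improvement")
    return AttemptOutcome(True, "committed", distances=new_distances)


def attempt_geodesic_rewire(net: nx.Graph, rng: np.random.Generator,
                            distances: np.ndarray) -> AttemptOutcome:
    """One geodesic proposal: distance-weighted pair, degree-weighted neighbours.

    ``distances`` must be the current all-pairs hop-count table; it is only
    read, and a refreshed copy is returned inside a committed outcome.
    """
    n = net.number_of_nodes()
    iu, ju = np.triu_indices(n, k=1)
    weights = distances[iu, ju]
    k = rng.choice(weights.size, p=weights / weights.sum())
    a, b = int(iu[k]), int(ju[k])

    nbrs_a = list(net.neighbors(a))
    deg_a = np.array([net.degree(x) for x in nbrs_a], dtype=float)
    c = nbrs_a[rng.choice(len(nbrs_a), p=deg_a / deg_a.sum())]
    nbrs_b = list(net.neighbors(b))
    deg_b = np.array([net.degree(x) for x in nbrs_b], dtype=float)
    d = nbrs_b[rng.choice(len(nbrs_b), p=deg_b / deg_b.sum())]
    return evaluate_geodesic_rewire(net, a, b, c, d, distances)


# ---------------------------------------------------------------------------
# controller
# ---------------------------------------------------------------------------

def run_rewiring(start: nx.Graph, config: RewiringConfig,
                 rng: np.random.Generator | None = None,
                 sequence_name: str | None = None,
                 network_replicate: int = 0,
                 run_replicate: int = 0) -> tuple[nx.Graph, Trajectory]:
    """Run one targeted rewiring experiment and record its trajectory.

    Attempts the configured algorithm repeatedly on a copy of ``start``.
    Every proposal — committed or not — counts toward the current window.
    The full property vector is recorded at attempt 0 and at every window
    boundary; the run stops when a completed window's success count falls
    below ``(1 - convergence) * window_size`` or the attempt cap is reached,
    and a terminal snapshot is always present.  Deterministic given the
    configured seed.
    """
    config.validate()
    if not nx.is_connected(start):
        raise ValueError("starting network must be connected")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    net = nx.Graph(start)
    net.graph.update(start.graph)
    name = sequence_name or start.graph.get("sequence_name", "")

    traj = Trajectory(name, network_replicate, run_replicate, config.algorithm, config)
    traj.snapshots.append((0, 0, measure_all(net)))

    distances = _distance_matrix(net) if config.algorithm == "geodesic" else None
    successes = 0
    window_successes = 0
    failure_cut = (1.0 - config.convergence) * config.window_size
    attempt = 0
    last_snapshot_attempt = 0
    while attempt < config.max_attempts:
        attempt += 1
        if config.algorithm == "assortativity":
            outcome = attempt_assortativity_swap(net, rng)
        elif config.algorithm == "clustering":
            outcome = attempt_clustering_rewire(net, rng)
        else:
            outcome = attempt_geodesic_rewire(net, rng, distances)
            if outcome.committed:
                distances = outcome.distances
        if outcome.committed:
            successes += 1
            window_successes += 1
        if attempt % config.window_size == 0:
            traj.snapshots.append((attempt, successes, measure_all(net)))
            last_snapshot_attempt = attempt
            if window_successes < failure_cut:
                break
            window_successes = 0
    if last_snapshot_attempt != attempt:
        traj.snapshots.append((attempt, successes, measure_all(net)))
    return net, traj
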