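"""Structural property measurements and the Gini coefficient.

Every node-level index is summarised by its mean and its Gini coefficient;
the Gini handles the heavily skewed distributions typical of social networks
better than the variance.  All measurements of one network are assembled into
a single :class:`PropertyVector` snapshot by :func:`measure_all`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "PropertyVector",
    "assortativity",
    "local_clustering",
    "mean_local_clustering",
    "transitivity",
    "geodesic_stats",
    "closeness_all",
    "betweenness_all",
    "eigenvector_all",
    "gini",
    "measure_all",
]


def assortativity(net: nx.Graph) -> Optional[float]:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Each edge contributes both orientations, so the two marginals coincide.
    Returns ``None`` (the undefined sentinel) when the endpoint degrees have
    zero variance, e.g. on regular graphs.
    """
    if net.number_of_edges() == 0:
        raise ValueError("assortativity undefined on an edgeless graph")
    deg = dict(net.degree())
    j = np.array([deg[u] for u, v in net.edges()], dtype=float)
    k = np.array([deg[v] for u, v in net.edges()], dtype=float)
    x = np.concatenate([j, k])
    y = np.concatenate([k, j])
    vx = x.var()
    if vx == 0.0:
        return None
    return float(((x * y).mean() - x.mean() * y.mean()) / vx)


def local_clustering(net: nx.Graph, node) -> float:
    """Fraction of the node's neighbour pairs that are themselves adjacent.

    Zero by convention for nodes of degree < 2.
    """
    return float(nx.clustering(net, node))


def mean_local_clustering(net: nx.Graph) -> float:
    """Mean of the local clustering coefficient over all nodes."""
    if net.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(net, count_zeros=True))


def transitivity(net: nx.Graph) -> float:
    """Global clustering: 3 x triangles / connected triples (0 when no triples)."""
    return float(nx.transitivity(net))


def _distance_matrix(net: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(net, nodelist=sorted(net.nodes()), format="csr")
    return shortest_path(sp.csr_matrix(adj), method="D", directed=False, unweighted=True)


def geodesic_stats(net: nx.Graph, distances: np.ndarray | None = None):
    """Mean geodesic, diameter and the all-pairs distance table.

    Distances are hop counts from breadth-first traversal; the mean is taken
    over unordered distinct node pairs.  Requires a connected graph.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("geodesic statistics need at least two nodes")
    if distances is None:
        if not nx.is_connected(net):
            raise ValueError("geodesic statistics require a connected graph")
        distances = _distance_matrix(net)
    n = distances.shape[0]
    mean = float(distances.sum() / (n * (n - 1)))
    diameter = int(distances.max())
    return mean, diameter, distances


def closeness_all(net: nx.Graph, distances: np.ndarray | None = None) -> np.ndarray:
    """Closeness centrality c_i = (n-1) / sum_j d(i, j), per node."""
    if distances is None:
        if not nx.is_connected(net):
            raise ValueError("closeness requires a connected graph")
        distances = _distance_matrix(net)
    n = distances.shape[0]
    if n < 2:
        raise ValueError("closeness needs at least two nodes")
    return (n - 1) / distances.sum(axis=1)


def betweenness_all(net: nx.Graph) -> np.ndarray:
    """Shortest-path betweenness, endpoints excluded, normalised by (n-1)(n-2)/2.

    Multiple shortest paths between a pair share the pair's unit weight
    equally (fractional counting).
    """
    if not nx.is_connected(net):
        raise ValueError("betweenness requires a connected graph")
    bc = nx.betweenness_centrality(net, normalized=True)
    return np.array([bc[v] for v in sorted(net.nodes())])


def eigenvector_all(net: nx.Graph) -> np.ndarray:
    """Principal eigenvector of the adjacency matrix, unit Euclidean norm.

    Computed by dense symmetric eigendecomposition; for a connected graph the
    Perron vector is strictly positive, and the sign is fixed accordingly.
    """
    if not nx.is_connected(net):
        raise ValueError("eigenvector centrality requires a connected graph")
    a = nx.to_numpy_array(net, nodelist=sorted(net.nodes()))
    w, v = np.linalg.eigh(a)
    vec = v[:, np.argmax(w)]
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    return vec / np.linalg.norm(vec)


def gini(values) -> float:
    """Gini coefficient of a non-negative distribution, in [0, 1).

    Defined as the mean absolute pairwise difference normalised by twice the
    mean, G = sum_ij |x_i - x_j| / (2 n^2 xbar); computed here by the
    equivalent O(n log n) sorted form.  Zero when the mean is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("gini needs at least one value")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0.0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(2.0 * (i * xs).sum() / (n * total) - (n + 1) / n)


# Stable serialization order for PropertyVector CSV columns.
PROPERTY_COLUMNS = (
    "n",
    "m",
    "degree_mean",
    "degree_gini",
    "assortativity",
    "mean_local_clustering",
    "transitivity",
    "geodesic_mean",
    "diameter",
    "closeness_mean",
    "closeness_gini",
    "betweenness_mean",
    "betweenness_gini",
    "eigenvector_mean",
    "eigenvector_gini",
)


@dataclass(frozen=True)
class PropertyVector:
    """One simultaneous snapshot of all tracked structural properties.

    ``assortativity`` is ``None`` on degree-regular graphs (zero endpoint
    variance), which serialises as an empty CSV cell.
    """

    n: int
    m: int
    degree_mean: float
    degree_gini: float
    assortativity: Optional[float]
    mean_local_clustering: float
    transitivity: float
    geodesic_mean: float
    diameter: int
    closeness_mean: float
    closeness_gini: float
    betweenness_mean: float
    betweenness_gini: float
    eigenvector_mean: float
    eigenvector_gini: float

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in PROPERTY_COLUMNS}

    def to_row(self) -> list:
        return ["" if (v := getattr(self, c)) is None else v for c in PROPERTY_COLUMNS]


def measure_all(net: nx.Graph) -> PropertyVector:
    """Measure every tracked property of a connected simple graph at once.

    The all-pairs distance table is computed once and shared between the
    geodesic and closeness measurements.
    """
    if not nx.is_connected(net):
        raise ValueError("measure_all requires a connected graph")
    n = net.number_of_nodes()
    m = net.number_of_edges()
    degrees = np.array([net.degree(v) for v in sorted(net.nodes())], dtype=float)
    geo_mean, diameter, dist = geodesic_stats(net)
    clo = closeness_all(net, distances=dist)
    bet = betweenness_all(net)
    eig = eigenvector_all(net)
    return PropertyVector(
        n=n,
        m=m,
        degree_mean=float(degrees.mean()),
        degree_gini=gini(degrees),
        assortativity=assortativity(net),
        mean_local_clustering=mean_local_clustering(net),
        transitivity=transitivity(net),
        geodesic_mean=geo_mean,
        diameter=diameter,
        closeness_mean=float(clo.mean()),
        closeness_gini=gini(clo),
        betweenness_mean=float(bet.mean()),
        betweenness_gini=gini(bet),
        eigenvector_mean=float(eig.mean()),
        eigenvector_gini=gini(eig),
    )
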