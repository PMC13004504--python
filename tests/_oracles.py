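"""Independent brute-force oracles for the structural metrics.

Everything here is written from the definitions in plain Python, without
touching the library code paths under test: Pearson sums for assortativity,
neighbour-pair enumeration for clustering, Floyd–Warshall for distances,
exhaustive simple-path enumeration for betweenness, and the O(n^2)
pairwise-difference form of the Gini coefficient.
"""

from itertools import combinations
from math import sqrt


def directed_degree_pairs(net):
    deg = {v: net.degree(v) for v in net.nodes()}
    pairs = []
    for u, v in net.edges():
        pairs.append((deg[u], deg[v]))
        pairs.append((deg[v], deg[u]))
    return pairs


def assortativity_oracle(net):
    """Pearson correlation over both orientations of every edge, by the sums."""
    pairs = directed_degree_pairs(net)
    n = len(pairs)
    sx = sum(x for x, _ in pairs)
    sy = sum(y for _, y in pairs)
    sxx = sum(x * x for x, _ in pairs)
    syy = sum(y * y for _, y in pairs)
    sxy = sum(x * y for x, y in pairs)
    varx = sxx / n - (sx / n) ** 2
    vary = syy / n - (sy / n) ** 2
    if varx == 0 or vary == 0:
        return None
    return (sxy / n - (sx / n) * (sy / n)) / sqrt(varx * vary)


def local_clustering_oracle(net, node):
    nbrs = list(net.neighbors(node))
    if len(nbrs) < 2:
        return 0.0
    links = sum(1 for a, b in combinations(nbrs, 2) if net.has_edge(a, b))
    return links / (len(nbrs) * (len(nbrs) - 1) / 2)


def mean_local_clustering_oracle(net):
    nodes = list(net.nodes())
    return sum(local_clustering_oracle(net, v) for v in nodes) / len(nodes)


def transitivity_oracle(net):
    triangles = 0
    triples = 0
    for v in net.nodes():
        d = net.degree(v)
        triples += d * (d - 1) // 2
        for a, b in combinations(list(net.neighbors(v)), 2):
            if net.has_edge(a, b):
                triangles += 1  # counts each triangle once per corner
    return triangles / triples if triples else 0.0


def floyd_warshall_oracle(net):
    nodes = sorted(net.nodes())
    inf = float("inf")
    dist = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in net.edges():
        dist[u][v] = dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == inf:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def geodesic_oracle(net):
    dist = floyd_warshall_oracle(net)
    nodes = sorted(net.nodes())
    lengths = [dist[u][v] for u, v in combinations(nodes, 2)]
    return sum(lengths) / len(lengths), max(lengths)


def closeness_oracle(net):
    dist = floyd_warshall_oracle(net)
    nodes = sorted(net.nodes())
    n = len(nodes)
    return [(n - 1) / sum(dist[u][v] for v in nodes if v != u) for u in nodes]


def _all_simple_paths(net, source, target):
    paths = []

    def extend(path):
        last = path[-1]
        if last == target:
            paths.append(list(path))
            return
        for nxt in net.neighbors(last):
            if nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([source])
    return paths


def betweenness_oracle(net):
    """Fractional shortest-path counting over exhaustively enumerated paths.

    Endpoints excluded, normalised by (n-1)(n-2)/2.
    """
    nodes = sorted(net.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(net, s, t)
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for interior in p[1:-1]:
                score[interior] += 1.0 / len(geodesics)
    norm = (n - 1) * (n - 2) / 2
    return [score[v] / norm if norm else 0.0 for v in nodes]


def gini_definitional(values):
    xs = list(values)
    n = len(xs)
    mean = sum(xs) / n
    if mean == 0:
        return 0.0
    return sum(abs(a - b) for a in xs for b in xs) / (2 * n * n * mean)
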