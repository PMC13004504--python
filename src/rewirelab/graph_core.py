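"""Graph and degree-sequence containers, file I/O, configuration-model sampling.

Networks are plain :class:`networkx.Graph` objects with 0-based contiguous
integer node ids.  Original node labels (from an edge-list file, or the
pre-relabelling ids of a giant component) are kept in ``G.graph["node_labels"]``,
a list mapping internal id -> original label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DegreeSequence",
    "read_edge_list",
    "write_edge_list",
    "read_degree_sequence",
    "write_degree_sequence",
    "degree_sequence_of",
    "configuration_model",
    "giant_component",
]


@dataclass(frozen=True)
class DegreeSequence:
    """A named multiset of node degrees.

    This is the only information carried from an empirical network into a
    rewiring experiment: starting networks are drawn from the configuration
    model on these degrees, never copied from the source graph.
    """

    name: str
    degrees: tuple[int, ...] = field(default_factory=tuple)

    def __init__(self, name: str, degrees: Sequence[int]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "degrees", tuple(int(d) for d in degrees))
        if len(self.degrees) == 0:
            raise ValueError("degree sequence is empty")
        if any(d < 1 for d in self.degrees):
            raise ValueError("all degrees must be >= 1 (isolated nodes carry no edges to rewire)")

    def __len__(self) -> int:
        return len(self.degrees)

    @property
    def total(self) -> int:
        return sum(self.degrees)

    @property
    def mean(self) -> float:
        return self.total / len(self.degrees)

    @property
    def has_even_sum(self) -> bool:
        return self.total % 2 == 0


def _parse_tokens(line: str):
    if "," in line:
        return [t.strip() for t in line.split(",") if t.strip()]
    return line.split()


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from a two-column edge-list file.

    One edge per line, two whitespace- or comma-separated node tokens; lines
    starting with ``#`` (and blank lines) are ignored.  Self-loops are
    dropped and parallel edges collapsed.  Node tokens are mapped to 0-based
    contiguous integers in order of first appearance; the original tokens are
    retrievable from ``G.graph["node_labels"]``.  The result need not be
    connected.
    """
    path = Path(path)
    labels: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    n_data_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _parse_tokens(line)
            if len(tokens) != 2:
                raise ValueError(f"{path}:{lineno}: expected two node tokens, got {len(tokens)}: {line!r}")
            n_data_lines += 1
            uv = []
            for tok in tokens:
                if tok not in labels:
                    labels[tok] = len(labels)
                uv.append(labels[tok])
            u, v = uv
            if u != v:  # self-loops dropped
                edges.append((u, v))
    if n_data_lines == 0:
        raise ValueError(f"{path}: no edges found")
    g = nx.Graph()
    g.add_nodes_from(range(len(labels)))
    g.add_edges_from(edges)  # Graph collapses parallels
    g.graph["node_labels"] = [lab for lab, _ in sorted(labels.items(), key=lambda kv: kv[1])]
    return g


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write one ``u v`` pair per line (internal integer ids, sorted)."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.edges()):
            fh.write(f"{u} {v}\n")


def read_degree_sequence(path: str | Path, name: str | None = None) -> DegreeSequence:
    """Read a degree sequence: one positive integer per line, ``#`` comments."""
    path = Path(path)
    degrees: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                degrees.append(int(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from exc
    return DegreeSequence(name or path.stem, degrees)


def write_degree_sequence(seq: DegreeSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in seq.degrees:
            fh.write(f"{d}\n")


def degree_sequence_of(net: nx.Graph, name: str = "") -> DegreeSequence:
    """Degree sequence of a network, listed per node id.

    The sum of the returned degrees equals twice the edge count (handshake
    lemma).
    """
    return DegreeSequence(name, [net.degree(v) for v in sorted(net.nodes())])


def configuration_model(seq: DegreeSequence, rng: np.random.Generator) -> nx.Graph:
    """Draw a simple graph from the configuration model on ``seq``.

    Degree stubs are matched uniformly at random; the resulting multigraph is
    then simplified by removing self-loops and collapsing parallel edges, so
    realised degrees can fall slightly below the requested ones.  The result
    may be disconnected — callers typically extract the giant component.
    """
    if not seq.has_even_sum:
        raise ValueError(f"degree sum must be even, got {seq.total}")
    multi = nx.configuration_model(list(seq.degrees), seed=rng)
    g = nx.Graph(multi)
    g.remove_edges_from(nx.selfloop_edges(g))
    g.graph["node_labels"] = list(range(g.number_of_nodes()))
    g.graph["sequence_name"] = seq.name
    return g


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component, relabelled 0..k-1.

    Ties between equally large components are broken in favour of the one
    containing the smallest node id.  Idempotent up to the relabelling: the
    giant component of a connected graph is the graph itself.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph has no giant component")
    best = max(nx.connected_components(net), key=lambda c: (len(c), -min(c)))
    old_labels = net.graph.get("node_labels")
    order = sorted(best)
    mapping = {old: new for new, old in enumerate(order)}
    g = nx.Graph()
    g.add_nodes_from(range(len(order)))
    g.add_edges_from((mapping[u], mapping[v]) for u, v in net.subgraph(best).edges())
    g.graph["node_labels"] = [old if old_labels is None else old_labels[old] for old in order]
    if "sequence_name" in net.graph:
        g.graph["sequence_name"] = net.graph["sequence_name"]
    return g
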