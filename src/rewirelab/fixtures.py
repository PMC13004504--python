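"""Synthetic degree sequences and canned toy graphs.

The rewiring experiments only consume degree sequences, so synthetic
sequences that match a target size, mean degree and degree Gini stand in for
downloaded empirical networks.  The lognormal family is used for skewed
(social-network-like) degree distributions because its Gini coefficient has
a closed form, G = 2*Phi(sigma/sqrt(2)) - 1, which makes the calibration
exactly invertible: sigma = sqrt(2) * Phi^{-1}((G+1)/2).

``REFERENCE_PROFILES`` lists (n, mean degree, degree Gini) triples matching
seven published small social networks (trust, board interlock, school
contact, collaboration, friendship, retweet and email graphs spanning
n = 101-610, mean degree 3.7-43 and degree Gini 0.25-0.53), so experiments of
the same scale can be run without any download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import networkx as nx
import numpy as np
from scipy.stats import norm

from .graph_core import DegreeSequence

__all__ = ["SequenceSpec", "synth_degree_sequence", "toy_graph", "REFERENCE_PROFILES"]

# (n, mean degree, degree Gini) of the seven reference social networks
REFERENCE_PROFILES: dict[str, tuple[int, float, float]] = {
    "filmtrust": (101, 14.8, 0.45),
    "boards": (131, 10.3, 0.28),
    "french_school": (153, 5.5, 0.25),
    "jazz": (198, 27.7, 0.35),
    "anu_residence": (217, 16.9, 0.25),
    "congress_twitter": (475, 43.0, 0.30),
    "eu_email": (610, 3.7, 0.53),
}


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a synthetic degree sequence.

    ``gini`` is the target degree Gini for the lognormal family; the
    poisson-like family's dispersion is fixed by ``mean_degree`` alone and
    takes no Gini target.
    """

    n: int
    mean_degree: float
    gini: Optional[float] = None
    family: Literal["lognormal", "poisson-like"] = "lognormal"
    name: str = ""

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("need at least 10 nodes")
        if not (1.0 <= self.mean_degree < self.n - 1):
            raise ValueError("mean degree must lie in [1, n-2]")
        if self.family == "lognormal":
            if self.gini is None or not (0.0 <= self.gini < 1.0):
                raise ValueError("lognormal family needs a target Gini in [0, 1)")
        elif self.family != "poisson-like":
            raise ValueError(f"unknown family {self.family!r}")


def lognormal_sigma_for_gini(g: float) -> float:
    """Shape parameter of a lognormal with Gini coefficient ``g``."""
    return float(np.sqrt(2.0) * norm.ppf((g + 1.0) / 2.0))


def synth_degree_sequence(spec: SequenceSpec, rng: np.random.Generator) -> DegreeSequence:
    """Draw a degree sequence matching ``spec``; deterministic given the rng state.

    Continuous draws are rounded to the nearest integer and clamped to a
    minimum degree of 1; if the sum ends up odd, one uniformly chosen node's
    degree is incremented (never decremented, preserving the minimum).
    Raises when clamping distorts the mean by more than 20% — the requested
    Gini is then infeasible at this mean degree.
    """
    spec.validate()
    if spec.family == "lognormal":
        sigma = lognormal_sigma_for_gini(spec.gini)
        mu = np.log(spec.mean_degree) - sigma**2 / 2.0
        raw = rng.lognormal(mean=mu, sigma=sigma, size=spec.n)
    else:
        raw = rng.poisson(lam=spec.mean_degree, size=spec.n).astype(float)
    degrees = np.maximum(np.rint(raw).astype(int), 1)
    # a node may not exceed n-1 neighbours in a simple graph
    degrees = np.minimum(degrees, spec.n - 1)
    # compare against the pre-clamp sample mean, so heavy-tail sampling noise
    # is not mistaken for clamping distortion
    if abs(degrees.mean() - raw.mean()) > 0.2 * raw.mean():
        raise ValueError(
            f"infeasible spec: rounding/clamping moves the mean from {raw.mean():.2f} "
            f"to {degrees.mean():.2f}, more than 20%"
        )
    if degrees.sum() % 2 == 1:
        degrees[rng.integers(spec.n)] += 1
    name = spec.name or f"{spec.family}-n{spec.n}"
    return DegreeSequence(name, degrees.tolist())


def _from_edges(n: int, edges) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    g.graph["node_labels"] = list(range(n))
    return g


def toy_graph(name: str) -> nx.Graph:
    """Return a small named test graph with canonical 0-based labelling."""
    builders = {
        "triangle": lambda: _from_edges(3, [(0, 1), (1, 2), (2, 0)]),
        "path3": lambda: nx.path_graph(3),
        "path4": lambda: nx.path_graph(4),
        "path5": lambda: nx.path_graph(5),
        "cycle5": lambda: nx.cycle_graph(5),
        "cycle6": lambda: nx.cycle_graph(6),
        # 6-cycle with a chord across opposite nodes 0 and 3
        "cycle6_chord": lambda: _from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (0, 3)]),
        "star4": lambda: nx.star_graph(3),
        # triangle with one pendant vertex
        "paw": lambda: _from_edges(4, [(0, 1), (1, 2), (2, 0), (2, 3)]),
        "complete4": lambda: nx.complete_graph(4),
        # two triangles joined by a 2-edge path through node 3
        "bridged_triangles": lambda: _from_edges(
            7, [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 5), (5, 6), (6, 4)]
        ),
    }
    if name not in builders:
        raise ValueError(f"unknown toy graph {name!r}; known: {sorted(builders)}")
    g = builders[name]()
    g.graph.setdefault("node_labels", list(range(g.number_of_nodes())))
    return g
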