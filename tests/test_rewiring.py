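"""The three rewiring operations and the window/convergence controller."""

import networkx as nx
import numpy as np
import pytest

from rewirelab import (
    AttemptOutcome,
    RewiringConfig,
    attempt_assortativity_swap,
    attempt_clustering_rewire,
    degree_sequence_of,
    mean_local_clustering,
    geodesic_stats,
    run_rewiring,
    toy_graph,
)
from rewirelab.metrics import _distance_matrix, assortativity
from rewirelab.rewiring import (
    evaluate_assortativity_swap,
    evaluate_clustering_rewire,
    evaluate_geodesic_rewire,
)


def edge_set(g):
    return set(map(frozenset, g.edges()))


def test_attempt_outcome_flag_must_match_reason():
    with pytest.raises(ValueError):
        AttemptOutcome(True, "no-improvement")


# --- assortativity -----------------------------------------------------------

def degree_gadget():
    """Graph holding an edge with endpoint degrees (4,1) and one with (3,2)."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (0, 3), (0, 4),        # deg(0)=4, deg(4)=1
                      (5, 6), (5, 2), (5, 3),                # deg(5)=3
                      (6, 1)])                               # deg(6)=2
    return g


def test_assortativity_swap_rearranges_to_higher_product():
    g = degree_gadget()
    deg = dict(g.degree())
    assert (deg[0], deg[4]) == (4, 1) and (deg[5], deg[6]) == (3, 2)
    before = edge_set(g)
    out = evaluate_assortativity_swap(g, (0, 4), (5, 6))
    assert out.committed
    # proposal joins the two high-degree nodes (0,5) and the two low ones (4,6)
    assert frozenset((0, 5)) in edge_set(g) and frozenset((4, 6)) in edge_set(g)
    assert dict(g.degree()) == deg
    assert edge_set(g) != before


def test_assortativity_swap_already_optimal_makes_no_change():
    g = degree_gadget()
    evaluate_assortativity_swap(g, (0, 4), (5, 6))
    before = edge_set(g)
    out = evaluate_assortativity_swap(g, (0, 5), (4, 6))
    assert out.reason == "already-optimal"
    assert edge_set(g) == before


def test_assortativity_swap_shared_node_is_degenerate():
    g = toy_graph("star4")
    out = evaluate_assortativity_swap(g, (0, 1), (0, 2))
    assert out.reason == "degenerate-selection"


def test_assortativity_on_star_never_commits():
    g = toy_graph("star4")
    rng = np.random.default_rng(0)
    for _ in range(50):
        out = attempt_assortativity_swap(g, rng)
        assert out.reason == "degenerate-selection"
    assert assortativity(g) == pytest.approx(-1.0)


def test_committed_swaps_raise_degree_product_sum(n150_network):
    """Every commit strictly raises sum of endpoint-degree products."""
    g = nx.Graph(n150_network)
    rng = np.random.default_rng(1)
    deg = dict(g.degree())

    def product_sum(h):
        return sum(deg[u] * deg[v] for u, v in h.edges())

    commits = 0
    for _ in range(2000):
        before = product_sum(g)
        if attempt_assortativity_swap(g, rng).committed:
            commits += 1
            assert product_sum(g) > before
            assert dict(g.degree()) == deg
    assert commits > 50


# --- clustering --------------------------------------------------------------

def test_clustering_rewire_closes_two_triangles():
    g = toy_graph("cycle6_chord")
    out = evaluate_clustering_rewire(g, 1, 2, 3, 4, 5)
    assert out.committed
    assert mean_local_clustering(g) == pytest.approx(7 / 9)
    assert sorted(d for _, d in g.degree()) == [2, 2, 2, 2, 3, 3]


def test_clustering_rewire_reverts_on_disconnect():
    g = toy_graph("path5")
    before = edge_set(g)
    out = evaluate_clustering_rewire(g, 0, 1, 2, 3, 4)
    assert out.reason == "would-disconnect"
    assert edge_set(g) == before


def test_clustering_rewire_rejects_duplicate_edge():
    g = toy_graph("cycle5")
    out = evaluate_clustering_rewire(g, 0, 1, 2, 3, 4)
    assert out.reason == "duplicate-edge"


def test_clustering_attempt_no_valid_path_on_star():
    g = toy_graph("star4")
    rng = np.random.default_rng(0)
    assert attempt_clustering_rewire(g, rng).reason == "no-valid-path"


def test_clustering_commits_strictly_increase_mean(n150_network):
    g = nx.Graph(n150_network)
    rng = np.random.default_rng(2)
    commits = 0
    for _ in range(1500):
        before = mean_local_clustering(g)
        if attempt_clustering_rewire(g, rng).committed:
            commits += 1
            assert mean_local_clustering(g) > before
    assert commits > 50


# --- geodesic ----------------------------------------------------------------

def test_geodesic_rewire_on_path_ends_rejects():
    """On the 4-path the forced neighbour edge (1,2) already exists, so the
    end-pair shortcut is rejected before any swap and nothing changes."""
    g = toy_graph("path4")
    d = _distance_matrix(g)
    before = edge_set(g)
    out = evaluate_geodesic_rewire(g, 0, 3, 1, 2, d)
    assert not out.committed and out.reason == "duplicate-edge"
    assert edge_set(g) == before


def test_geodesic_rewire_reverts_on_disconnect():
    # 5-path, shortcut the ends via interior neighbours: {0,4} splits off
    g = toy_graph("path5")
    d = _distance_matrix(g)
    before = edge_set(g)
    out = evaluate_geodesic_rewire(g, 0, 4, 1, 3, d)
    assert out.reason == "would-disconnect"
    assert edge_set(g) == before


def test_geodesic_rewire_rejects_tie_on_cycle():
    g = toy_graph("cycle6")
    d = _distance_matrix(g)
    out = evaluate_geodesic_rewire(g, 0, 3, 1, 4, d)  # relabelled 6-cycle, mean unchanged
    assert out.reason == "no-improvement"
    assert edge_set(g) == edge_set(toy_graph("cycle6"))


def test_geodesic_rewire_commits_on_bridged_triangles():
    g = toy_graph("bridged_triangles")
    d = _distance_matrix(g)
    mean_before, _, _ = geodesic_stats(g, d)
    out = evaluate_geodesic_rewire(g, 0, 5, 1, 6, d)
    assert out.committed
    mean_after, _, _ = geodesic_stats(g, out.distances)
    assert mean_after < mean_before
    assert sorted(d for _, d in g.degree()) == [2, 2, 2, 2, 2, 3, 3]


def test_geodesic_rewire_existing_edge_rejected():
    g = toy_graph("cycle6")
    d = _distance_matrix(g)
    assert evaluate_geodesic_rewire(g, 0, 1, 5, 2, d).reason == "duplicate-edge"


# --- controller --------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [dict(window_size=0), dict(convergence=0.0), dict(convergence=1.0), dict(max_attempts=0)],
)
def test_invalid_configs_rejected(kwargs):
    base = dict(algorithm="assortativity", window_size=5, convergence=0.9, max_attempts=10, seed=0)
    base.update(kwargs)
    cfg = RewiringConfig(**base)
    with pytest.raises(ValueError):
        cfg.validate()


def test_default_configs_follow_window_conventions():
    cfg = RewiringConfig.default_for("assortativity", 414)
    assert (cfg.window_size, cfg.max_attempts, cfg.convergence) == (83, 4140, 0.9)
    cfg = RewiringConfig.default_for("geodesic", 414)
    assert (cfg.window_size, cfg.max_attempts) == (42, 414)


def test_complete_graph_terminates_after_one_window():
    """On K4 no assortativity swap can ever commit, so the run stops at attempt w."""
    g = toy_graph("complete4")
    cfg = RewiringConfig("assortativity", window_size=6, max_attempts=60, seed=0)
    final, traj = run_rewiring(g, cfg)
    assert [s[0] for s in traj.snapshots] == [0, 6]
    assert traj.snapshots[-1][1] == 0
    assert edge_set(final) == edge_set(g)


def test_run_is_reproducible_and_monotone(n150_network):
    cfg = RewiringConfig("assortativity", window_size=50, max_attempts=400, seed=42)
    final1, traj1 = run_rewiring(n150_network, cfg)
    final2, traj2 = run_rewiring(n150_network, cfg)
    assert edge_set(final1) == edge_set(final2)
    rows1 = [tuple(r) for r in traj1.rows()]
    rows2 = [tuple(r) for r in traj2.rows()]
    assert rows1 == rows2

    attempts = [s[0] for s in traj1.snapshots]
    successes = [s[1] for s in traj1.snapshots]
    assert attempts == sorted(attempts) and len(set(attempts)) == len(attempts)
    assert successes == sorted(successes)
    assert attempts[-1] <= cfg.max_attempts
    r_values = [s[2].assortativity for s in traj1.snapshots]
    assert all(a <= b for a, b in zip(r_values, r_values[1:]))
    # degree distribution is untouched along the trajectory
    assert len({(s[2].degree_mean, s[2].degree_gini) for s in traj1.snapshots}) == 1
    assert degree_sequence_of(final1).degrees == degree_sequence_of(n150_network).degrees


def test_geodesic_run_monotone_decreasing(n150_network):
    cfg = RewiringConfig("geodesic", window_size=30, max_attempts=90, seed=3)
    final, traj = run_rewiring(n150_network, cfg)
    l_values = [s[2].geodesic_mean for s in traj.snapshots]
    assert all(a >= b for a, b in zip(l_values, l_values[1:]))
    assert l_values[-1] < l_values[0]


def test_trajectory_csv_schema(tmp_path, n150_network):
    cfg = RewiringConfig("clustering", window_size=40, max_attempts=80, seed=5)
    _, traj = run_rewiring(n150_network, cfg)
    out = tmp_path / "traj.csv"
    traj.write_csv(out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("# rewirelab trajectory")
    header = lines[1].split(",")
    assert header[:4] == ["sequence", "network_replicate", "run_replicate", "algorithm"]
    assert "assortativity" in header and "geodesic_mean" in header
    assert len(lines) == 2 + len(traj.snapshots)
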