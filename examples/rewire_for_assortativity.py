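"""Raise degree assortativity by degree-preserving edge swaps.

Builds a configuration-model network from a synthetic contact-network-like
degree sequence, then repeatedly re-pairs random edge pairs so high-degree
nodes connect to each other, tracking the full property vector along the way.
"""

import numpy as np

from rewirelab import (
    RewiringConfig,
    SequenceSpec,
    configuration_model,
    giant_component,
    run_rewiring,
    synth_degree_sequence,
)

rng = np.random.default_rng(0)
seq = synth_degree_sequence(SequenceSpec(n=153, mean_degree=5.5, gini=0.25, name="demo"), rng)
net = giant_component(configuration_model(seq, rng))

cfg = RewiringConfig.default_for("assortativity", net.number_of_edges(), seed=1)
final, traj = run_rewiring(net, cfg)

print(f"{'attempt':>8s} {'commits':>8s} {'r':>8s} {'clustering':>11s} {'geodesic':>9s}")
for attempt, successes, pv in traj.snapshots:
    print(f"{attempt:8d} {successes:8d} {pv.assortativity:8.3f} "
          f"{pv.mean_local_clustering:11.3f} {pv.geodesic_mean:9.3f}")

print()
print("r climbs monotonically (only strictly improving swaps commit) while the")
print("degree sequence never changes; watch clustering and the mean geodesic")
print("drift upward as side effects of sorting edges by degree.")
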