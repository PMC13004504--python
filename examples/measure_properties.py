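"""Measure the full structural-property vector of a small graph.

Builds the 'paw' toy graph (a triangle with one pendant vertex) and prints
every tracked property: degree/assortativity/clustering/geodesic summaries
and the mean and Gini coefficient of three node centralities.
"""

from rewirelab import measure_all, toy_graph

net = toy_graph("paw")
pv = measure_all(net)
for name, value in pv.to_dict().items():
    print(f"{name:22s} {value}")

print()
print("The Gini values summarise how unequally each centrality is spread over")
print("nodes (0 = all nodes equal); assortativity < 0 says high-degree nodes")
print("attach to low-degree ones, as the pendant vertex forces here.")
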