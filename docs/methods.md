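# Methods

## Scope and model

`rewirelab` studies how the structural properties of small social networks
(n ≈ 100–600) constrain one another when the degree sequence is held fixed.
The degree sequence is treated as the identity of a network family: starting
networks are drawn from the configuration model on that sequence, and three
separate algorithms then rewire edges — never degrees — to push one property
at a time: degree assortativity up, mean local clustering up, or mean
geodesic down. Because every committed swap strictly improves the target and
preserves simplicity and connectivity, a trajectory of snapshots is a
monotone walk through the property space reachable from that degree
sequence, and the co-movement of the *other* properties along the walk is
the object of study.

## Starting networks

The configuration model is realised by uniform stub matching followed by
simplification (self-loops removed, parallel edges collapsed), rather than
by rejection sampling of simple graphs. This always terminates and its
small degree deficit (for sequences with maximum degree well below n, under
5% of total degree on average) matches the small gaps observed between
empirical degree sequences and their randomised counterparts. The giant
component of each draw is the starting network; all post-extraction graphs
are connected, with 0-based contiguous node ids and the pre-extraction
labels kept in a side mapping. Ties between equally large components are
broken toward the component containing the smallest node id, purely for
determinism. Draws whose giant component is small are accepted as-is.

## Rewiring operations

**Assortativity.** Two distinct edges are chosen uniformly; selections
sharing a node are counted as failed attempts (`degenerate-selection`), not
silently resampled — they are wasted proposals and belong in the window's
failure count. The proposal joins the two highest-degree and two
lowest-degree of the four endpoints. Since a degree-preserving swap leaves
the marginal moments of the edge-end degree distribution untouched, the
change in Pearson assortativity has the sign of the change in Σₑ jₑkₑ;
the commit rule "strictly larger product sum" therefore guarantees r is
strictly increasing across commits. Ties (including tied endpoint degrees
that make the optimal pairing non-unique) are rejected as `already-optimal`.

**Clustering.** A centre node A with degree ≥ 2 is chosen uniformly, two
incident edges give neighbours u and v, and one further uniform step beyond
each (excluding already-used nodes) yields the 5-node path p–u–A–v–q. If
either extension has no eligible neighbour the attempt fails
(`no-valid-path`). The rewire removes (p,u) and (v,q) and adds (u,v) and
(p,q); the duplicate check applies to the two added edges. Because the
removed edges can destroy triangles, the mean local coefficient is
recomputed over the affected nodes (the four moved endpoints and their
neighbourhoods — every node whose triangle count can change lies in this
set) and compared exactly: local coefficients are summed as rationals
2·Tᵢ/(dᵢ(dᵢ−1)) with `fractions.Fraction`, so floating-point noise can
never commit a zero-change proposal. Nodes of degree < 2 contribute 0 to
the mean (they are not excluded), keeping C̄ defined on every graph.

**Geodesic.** A node pair (A,B) is sampled with probability proportional to
its current distance — rather than always taking the most distant pair — so
that no distance stratum has zero selection probability; one neighbour of
each (C of A, D of B) is sampled with probability proportional to degree.
The proposal removes (A,C) and (B,D) and adds the shortcut (A,B) plus
(C,D). Non-distinct selections and already-present edges are rejected with
the matching reason; otherwise the swap is applied tentatively, the
all-pairs distance table recomputed, and the swap kept only if the mean
geodesic strictly fell. The distance table (integer hop counts via
breadth-first search in `scipy.sparse.csgraph`) is recomputed in full for
each tentative evaluation; the committed table is carried forward so pair
sampling always uses current distances. Distance sums are integers in
floating point, so the strict comparison is exact.

## Controller

Attempts run in windows of `window_size` proposals; every proposal —
committed, rejected or degenerate — counts. Defaults: window ⌈0.2·M⌉ and cap
10·M for assortativity and clustering; window ⌈0.1·M⌉ and cap M for
geodesic, whose two shortest-path recomputations per attempt dominate its
cost. The run stops when a completed window's success count falls below
(1 − convergence)·window_size (convergence defaults to 0.9, i.e. stop under
10% successes) or at the cap. The full property vector is recorded at
attempt 0 and every window boundary, and a terminal snapshot is always
present even when the cap lands mid-window. Runs are pure functions of
(starting network, configuration, seed).

## Measurements

Assortativity is the Pearson correlation of endpoint degrees over both
orientations of every edge, computed directly from the definitional sums;
on degree-regular graphs the variance is zero and an undefined sentinel
(`None`, an empty CSV cell) is returned. Closeness is the inverse form
cᵢ = (n−1)/Σⱼd(i,j) — with distances fixed and finite on connected graphs
this is the standard convention and the one under which "closeness falls as
geodesics rise" reads correctly. Betweenness uses endpoint-excluded
fractional counting normalised by (n−1)(n−2)/2, so values are comparable
across network sizes and sit near zero for ~150-node graphs. Eigenvector
centrality is the principal eigenvector of the adjacency matrix with unit
Euclidean norm and non-negative entries; it is obtained by dense symmetric
eigendecomposition, which at these sizes (n ≤ ~600) is exact and faster
than iterating to a tolerance. The Gini coefficient uses the O(n log n)
sorted form, which the tests require to agree with the O(n²)
pairwise-difference definition; it is scale-invariant, zero exactly for
constant input, and defined as 0 when the mean is 0. Standard computations
(clustering, transitivity, betweenness, graph containers, configuration
model) are delegated to networkx; distances to scipy; assortativity, Gini
and the property-vector assembly are implemented here and cross-checked in
the test suite against brute-force oracles and, where available, networkx's
independent implementations.

## Synthetic degree sequences

The generator draws lognormal degrees because the lognormal Gini has the
closed form G = 2Φ(σ/√2) − 1, making the (mean, Gini) calibration exactly
invertible: σ = √2·Φ⁻¹((G+1)/2), μ = ln(k̄) − σ²/2. Draws are rounded,
clamped to ≥ 1 (and ≤ n−1), and parity-repaired by incrementing one
uniformly chosen degree — increments only, so the minimum degree survives.
If clamping distorts the realised mean by more than 20% the request is
rejected as infeasible. A poisson-like family covers low-variation
sequences; its dispersion is fixed by the mean, so it takes no Gini target.
The seven bundled reference profiles span n = 101–610, mean degree 3.7–43
and degree Gini 0.25–0.53 — the ranges of the small empirical social
networks this toolkit is aimed at — and their configuration-model giants
land in the empirical density range 0.006–0.148.

What the synthetic sequences do **not** emulate: degree correlations,
community structure, or any higher-order structure of real networks — the
configuration model destroys all of that by design, which is exactly why it
is the right null here. Passing tests on synthetic sequences therefore
demonstrate that the algorithms behave correctly for degree sequences *like*
the empirical ones (size, density, degree inequality), not that any
particular empirical network's trajectory is reproduced;
`reproduce_from_edge_lists()` reruns the design on real files when the user
has them.

## Experiment design and problem sizes

The full crossed design is sequences × networks-per-sequence (default 10) ×
repetitions (default 10) × algorithms, with per-run seeds derived by feeding
(master seed, sequence index, network index, repetition index, algorithm
index) through `numpy.random.SeedSequence`, so any subset of runs is
reproducible in isolation and reruns are byte-identical. Starting networks
are persisted as edge lists so their measured properties can be audited
against the summary table. Individual run failures are logged and counted,
never fatal to the batch. Plots are advisory; no numeric check reads from
an image.

The bundled tests and the acceptance script use scaled instances chosen to
exercise the same regimes at desk scale: the n=153-profile sequence (mean
degree 5.5, Gini 0.25) for assortativity and clustering runs and the sparse
n=610 profile (mean degree 3.7, Gini 0.53) for geodesic runs, with reduced
replicate counts for the orchestration tests.

## Known limitations

- Undirected, unweighted, simple graphs only; bipartite structure must be
  projected before use.
- Only the three stated directions (r up, C̄ up, ℓ down) are implemented;
  there is no multi-property targeting or annealing.
- The geodesic algorithm's full-table recomputation costs O(n·(n+M)) per
  attempt; its deliberately small attempt budget (M) is what keeps runs
  tractable, and on short-diameter networks it often terminates with modest
  improvement — an honest property of the method, not a defect.
- Assortativity is undefined (sentinel) on regular graphs; downstream
  aggregation skips the empty cells.
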