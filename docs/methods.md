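# Methods

## Record model and qualitative conversion

A record is one study's reported connectivity change for one unordered
region pair, carrying either an explicit direction (±1, patients vs
controls) or a Pearson correlation *r* ∈ (−1, 1). Quantitative values are
mapped through the Fisher transform *z* = artanh(*r*) and signed by *z*.
The two-category increase/decrease conversion has no "no change" class, so
*z* = 0 is unclassifiable and raises; an optional tie threshold τ (default
0) widens the unclassifiable band to |*z*| ≤ τ for sensitivity analyses.
Only connectivity-strength indicators (FC, SC, gFCD, lFCD, EC, ReHo)
become edges; network-level summary metrics and unknown statistics are
ingestible but excluded from graph construction by default.

Region labels resolve case-insensitively against a controlled vocabulary of
20 glossed codes, extensible from config (the vocabulary is deliberately
open to a configured 21st code). A raw-label merge map collapses anatomical
subdivisions (parietal subdivisions → parietal lobe; peri-rolandic and
adjacent midline clusters → sensorimotor cortex; thalamic subnuclei →
thalamus; striato-pallidal nuclei → basal ganglia) before canonical pair
ordering; records whose endpoints merge into the same region are dropped.
Records are not weighted by cohort size: study *n* is bookkeeping only, and
a pair reported with both signs is a conflict whose records are excluded
(default) or majority-voted (config).

## Centralities

Degree centrality is the distinct-neighbour count; a multiplicity-weighted
variant (counting supporting records per edge) exists because a degree
threshold applied to literature networks can plausibly operate on either
quantity. Betweenness is the fractional (Brandes) form — each pair {j, k}
contributes the fraction of its shortest paths through *i* — normalised by
(g−1)(g−2)/2 so values lie in [0, 1]; this is the form whose magnitudes
match the hub-category thresholds used below. A literal raw-path-count
mode is provided for comparison but is not used by the pipeline. Both are
checked in the test suite against an independent brute-force shortest-path
enumerator built on BFS predecessor DAGs.

## Stochastic node reduction (method 1)

The reduction deletes *termination nodes* — nodes that cannot influence the
rest of the network because no shortest path between two other nodes passes
through them. Each iteration (i) partitions the current subgraph by
asynchronous label propagation (LPA), (ii) marks every node with zero
betweenness in the whole current subgraph **or** within its community's
induced subgraph, (iii) deletes the marked nodes; the process stops at the
first iteration that marks none, and collapsing below two nodes is a
degenerate outcome (excluded, with a logged count, from enumeration
tallies).

Two design choices here were genuinely open:

* **Source of stochasticity.** Whole-graph zero-betweenness pruning alone
  is deterministic, and the layout cannot change topology, so the only
  named stochastic component that can diversify outcomes is the community
  partition. Scoring termination *within* communities makes the partition
  operative: a community split can strand a node at the edge of its
  community even when it carries shortest paths globally. Keeping the
  whole-graph criterion in the union guarantees that every surviving node
  has positive betweenness in the reduced network.
* **Determinism and idempotence.** Each iteration's LPA seed is a hash of
  the current graph content together with the run seed (not a sequential
  RNG stream), and LPA itself rebuilds its input in canonical node order
  because the asynchronous sweep is sensitive to insertion order. A run is
  therefore a pure function of (graph, seed), and re-reducing a reduced
  network replays the exact partition that certified its stability — the
  reduction is idempotent by construction.

On vertex-transitive graphs the outcome distribution inherits the
automorphism symmetry: outcomes in one orbit are equiprobable. The test
suite checks this on the 3-cube, whose non-degenerate proper outcomes are
exactly its six C4 faces with uniform frequencies (chi-square), and on
cycles and the octahedron, which either survive whole or collapse.
Enumeration over seeds b..b+n−1 reports per-signature probabilities and a
chi-square uniformity statistic over the observed signatures (α = 0.01);
configuration signatures are SHA-256 hashes of the sorted surviving node
and edge lists, invariant to relabeling order.

Configurations are categorised by normalised betweenness: Category 1,
exactly one node above 0.8 (dominant hub); Category 2, at least two nodes
in (0.5, 0.8] and none above 0.8 (hub pair/group); Category 3, all below
0.5 (diffuse). Precedence is 1 > 2 > 3, and profiles matching no class
(one mid-band node; two nodes above 0.8; values exactly 0.5) fall to
Category 3 with a warning — the boundaries leave these cases genuinely
unspecified, and warn-and-demote is the conservative completion.

A note on trees: every tree has zero-betweenness leaves, so termination
pruning strips any tree to nothing — the deterministic outcome for tree
inputs is the degenerate error, identically for every seed.

## Core extraction (method 2) and core modes

The core is the induced subgraph on nodes with degree strictly greater
than the threshold (default 10, in the configured degree mode). Core modes
are enumerated with the same reduction contract as the whole-brain stage.
When the core is (near-)complete, every node has zero betweenness and
reduction degenerates, so a clique-like core legitimately reports zero
distinct modes.

## Tract-constrained sign consistency

A tract map is a declarative unordered adjacency over the core regions —
an input (YAML), never derived from imaging. Along a chain of
fiber-connected regions, signed changes compose multiplicatively; the rule
is stated for two-edge chains and is generalised here in the minimal way:
the sign a network implies for a non-adjacent pair is the edge-sign product
over *shortest* tract paths, with disagreement between distinct shortest
paths (or disconnection) yielding an indeterminate implication, which
counts as a violation. In a structurally balanced network (every cycle's
sign product positive) no connected pair is indeterminate; the suite
verifies this exhaustively on all connected ≤ 5-node graphs under
polarity-product sign assignments.

The consistency report gives both the satisfied fraction over evaluated
changes and a pre-exclusion fraction whose denominator also counts
conflict-excluded changes (treating exclusion as satisfaction), since
either denominator convention is defensible when headline percentages are
quoted.

`search_max_consistent` enumerates connected edge subsets of the tract map
in increasing size; subset edges whose pair is directly observed carry the
observed sign, other edges range over both signs. The maximiser of the
consistency fraction is returned, ties broken toward fewer edges and then
lexicographic signature; enumeration stops early once a perfect candidate
exists at the current size (no larger subset can beat 1.0, and smaller
sizes were already swept). Exhaustive mode is guarded at 16 tract edges;
beyond that a seeded hill-climb (edge toggles and free-sign flips, with
restarts) is used, and exhaustive-vs-greedy dominance is asserted in tests.
Mean core betweenness across network modes is the arithmetic per-region
mean of normalised betweenness over a common node set.

## Synthetic corpus generator

The generator emulates the corpus shape the pipeline targets: 15 studies
over 21 regions with mixed indicators and modalities, a planted 6-region
high-degree core, and signed edges with controlled frustration. Study
cohort sizes are drawn uniformly from 10–60 patients/controls, giving
pooled totals of the right order without claiming to match any real corpus.

Edge planting: intra-core pairs always receive a record (the core is a
clique at the record level), core↔periphery pairs with probability
`p_core_edge` (default 0.7), periphery pairs with `p_periphery_edge`
(default 0.08). Expected simple degrees at the defaults are 15.5 for core
and ≈ 5.3 for periphery nodes, so exact recovery of the planted core by
the degree-10 filter succeeds in roughly 97 % of seeds; an applied-to-all
core-involving probability of 0.7 would put several percent of core nodes
below the threshold per seed and make reliable recovery impossible, which
is why the intra-core support is planted with certainty. A spec whose
expected core degree cannot exceed the threshold is rejected as
infeasible.

Signs: each region carries a latent ±1 polarity and an edge's true sign is
the product of its endpoint polarities, so the planted assignment is
structurally balanced and sign propagation is exactly consistent; each
observed sign then flips independently with probability
`frustration_rate`. The tract map is the planted intra-core support
(connected by construction), and the returned ground truth (core
membership, edges, true signs, flip locations) is the oracle for recovery
tests. Generation is bit-reproducible from the seed.

What the generator does *not* emulate: spatially correlated reporting,
study-quality heterogeneity, region-coverage bias, lateralisation, or any
time-series signal — passing tests demonstrate pipeline correctness on
planted structure, not neuroscientific validity on real corpora.

## Problem sizes and numerics

Default enumeration sizes are 500 whole-brain and 100 core reduction runs
in the pipeline config; the test suite and the acceptance script use
100–1000 runs and 100 generator seeds, which is ample for the tallies and
rates they assert. Betweenness zero-tests compare exactly against 0.0
(Brandes accumulates nonzero contributions only for on-path nodes, so no
tolerance is needed). Chi-square uniformity uses the observed signatures
as categories at α = 0.01; a single observed signature is reported as
trivially uniform (statistic 0, p = 1). All file outputs of the pipeline
are written atomically (temp-then-rename), and report JSON is validated
by the shipped pydantic schema.

## Known limitations

* The stochastic mechanism that diversifies reduced configurations is an
  adopted interpretation (community-scoped termination); other readings
  (reduction-order effects, record resampling) would change the outcome
  distribution on dense graphs.
* Vote-counting of signed findings ignores effect sizes and study
  weights; this is deliberate scope, not an omission to fix by pooling.
* The shipped six-region tract map is schematic; real analyses should
  supply a tractography-informed map.
* Sign propagation uses shortest tract paths only; longer detours carry no
  evidence in this model.
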