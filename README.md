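# jmenet

Network meta-analysis of resting-state functional-connectivity findings in
juvenile myoclonic epilepsy (JME).

Individual imaging studies report connectivity changes between pairs of
brain regions — as functional connectivity (FC), structural-neighbour
connectivity (SC), functional connectivity density (gFCD/lFCD), effective
connectivity (EC), or regional homogeneity (ReHo) — but each study covers
only a few regions. `jmenet` pools such per-study region-pair findings into
one signed whole-brain graph and asks which regions dominate its structure:

1. **Ingest & harmonise.** Per-study records (study, modality, indicator,
   region pair, direction or Pearson *r*) are validated against a
   controlled 21-region vocabulary. Quantitative indicators are reduced to
   qualitative signed changes via the Fisher transform
   *z* = ½·ln((1+*r*)/(1−*r*)); anatomical label merges (e.g. putamen +
   caudate + globus pallidus → basal ganglia) are applied; pairs reported
   with both increased and decreased connectivity are excluded as
   conflicts.
2. **Whole-brain network.** One undirected edge per reported region pair,
   carrying a sign (where studies agree) and a record multiplicity. Node
   importance is profiled by degree centrality
   *C<sub>D</sub>*(*i*) = Σ<sub>j</sub> *x<sub>ij</sub>* and betweenness
   centrality *C<sub>B</sub>*(*i*) — the fraction of shortest paths between
   other node pairs passing through *i*, normalised by (g−1)(g−2)/2.
3. **Stochastic node reduction.** Repeatedly: partition the surviving
   graph into communities by seeded asynchronous label propagation, then
   delete every *termination node* (zero betweenness in the whole graph or
   within its community) until an iteration deletes nothing. Because the
   partition is stochastic, repeated seeded runs yield a distribution over
   distinct reduced configurations, each classified by how betweenness
   concentrates (single hub with *C<sub>B</sub>* > 0.8; hub pair in
   (0.5, 0.8]; diffuse).
4. **Core extraction.** Nodes with degree > 10 form the core network.
5. **Tract-constrained sign consistency.** Given a white-matter tract map
   over the core, signs compose multiplicatively along fiber chains (A–B
   increased and B–C decreased imply A–C decreased). The package searches
   the connected tract-admissible signed networks for the one satisfying
   the largest fraction of observed changes.

A seeded synthetic-corpus generator with planted core, balanced signs and
controlled frustration makes every stage testable end to end.

## Worked example

```bash
jmenet simulate --out demo --seed 7
cat > demo/config.yaml <<EOF
records: demo/records.csv
registry: demo/registry.yaml
tracts: demo/tracts.yaml
out_dir: demo/out
seed: 7
n_runs: 200
n_core_runs: 50
EOF
jmenet run --config demo/config.yaml
```

prints

```
synthetic corpus (85 records) -> demo
report -> demo/out/report.json
core regions: ['R11', 'R12', 'R13', 'R16', 'R17', 'R18']; 1 whole-brain configurations; 0 core modes
```

The simulated corpus planted a 6-region core (`ground_truth.json`), and the
degree filter recovered exactly those six regions. `demo/out/report.json`
additionally records a consistency fraction of 1.0 (15 of 15 observed core
changes satisfied) with the recovered signed network
`{R11-R13: +, R12-R13: +, R12-R18: +, R13-R16: −, R17-R18: +}` — at zero
planted frustration the sign-propagation search reproduces every planted
sign from a minimal spanning set of tract edges. The dense synthetic
whole-brain graph reduces to a single stable configuration (category 3,
diffuse betweenness), and the clique-like synthetic core collapses under
further reduction, so no distinct core modes are reported at these
conditions.

Other subcommands: `ingest`, `build`, `reduce`, `core`, `consistency`
(see `jmenet --help`). A schematic six-region tract map for the canonical
core (Tha, Cere, BG, SMA, VC, PFC) ships as a convenience fixture.

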