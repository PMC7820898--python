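# plasmonet

From true single-cell gene-expression time series to "Waddington
landscape" state-machine Petri nets.

## The problem

Most single-cell studies sacrifice each cell at measurement, so gene
expression dynamics must be *inferred* from population snapshots under
strong assumptions (unidirectional differentiation, history-free
transitions). Giant multinucleate plasmodia of *Physarum polycephalum*
escape this limit: their vigorously mixed cytoplasm lets one repeatedly
sample the *same* cell, yielding genuine time series of a 35-gene
expression panel per cell — before and hourly after a far-red light
pulse that triggers the commitment to sporulation.

`plasmonet` implements the analysis route from such measurements to a
discrete dynamic model, for researchers analyzing multi-replicate
single-cell expression time courses:

1. **Preprocessing** — each RT-PCR measurement is normalized to its
   median over the gene panel, then each gene to its geometric mean
   over all retained values; replicate quality is summarized by the
   x-fold deviation `r = x / mean(replicate group)` (for a pair,
   `r₁ + r₂ = 2` exactly) with quantile tables, a two-fold concordance
   filter, and wholesale exclusion of discordant plasmodia.
2. **Discretization** — hierarchical clustering of the per-cell-timepoint
   expression vectors, cut by the SIMPROF similarity-profile permutation
   test: terminal, non-significant nodes are the discrete
   *gene-expression states*.
3. **Trajectories** — each cell's ordered state sequence on the 1 h grid.
4. **State-machine Petri net** — one *place* per state, one *transition*
   per observed ordered transit between different states (one pre-place,
   one post-place, arc weights 1). A start place C0 distributes the
   single token over observed initial states via immediate transitions.
   With one token the net is isomorphic to its reachability graph — the
   Markov chain of states a cell can traverse. Analyses: sources, sinks
   (terminal states), connected components, relative state frequency and
   residence-time stability, minimal T-invariants (= elementary directed
   cycles, enumerated by Johnson's algorithm and cross-checked against a
   brute-force oracle), token-game simulation, and export to ANDL
   (Snoopy-compatible) and GraphViz DOT.
5. **Visual analytics** — classical (Torgerson) multidimensional scaling
   with percent variance per coordinate, and discretized per-cell
   kinetics curves `log10(profile_state(t) / profile_state(0))`.

A **synthetic-data generator** reproduces the study design (24 cells,
11 hourly time points, 2 biological samples × 2 technical replicates,
35-gene panel with up-/down-regulated, condition-independent
"pcnA-group" and reference genes) around a planted Markov chain of
states, so every stage is testable against known ground truth. The
observed trajectory table of all 24 cells is packaged as a fixture.

## Worked example

```python
import plasmonet as pn

table = pn.table2_fixture()                 # 24 observed cell trajectories
net = pn.annotate_net(pn.build_net(table), table)
summary = pn.net_summary(net, n_genes=35, n_timepoints=11, n_cells=24)
print(summary.n_places, summary.n_transitions, round(summary.t_per_p, 2))
```

prints

```
111 159 1.43
```

— the 264 cell-timepoints fall into 111 distinct expression states
connected by 159 distinct transits; about 1.43 transits leave or enter
per state, reflecting branching and re-joining paths rather than one
smooth route. Continuing,

```python
analysis = pn.graph_analysis(net)
print(sorted(analysis.sinks & {s for r in table.subset(condition="far_red") for s in r.states}))
print(len(pn.minimal_t_invariants(net)))
```

```
[71, 76, 77, 78, 79, 95]
7
```

— the 16 light-stimulated cells converge onto six terminal (sink)
states, and the net contains 7 minimal T-invariants: elementary cycles
of spontaneous, reversible state switching. The `examples/` directory
holds one short narrative script per capability (net construction,
synthetic round trip, replicate QC, MDS/kinetics, token game); a thin
CLI (`plasmonet run --input fixture:table2 --out OUT`, plus `simulate`,
`normalize`, `cluster`, `petrinet`, `mds`, `kinetics` subcommands)
wraps the same functions for shell use.

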