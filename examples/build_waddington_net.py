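"""Build the Waddington-landscape Petri net from the packaged trajectories.

The packaged table holds the observed state trajectories of 24 plasmodial
cells (8 dark controls, 16 far-red stimulated) over 11 hourly time points.
Each distinct state becomes a place, each observed transit a transition.
"""

import plasmonet as pn

table = pn.table2_fixture()
net = pn.annotate_net(pn.build_net(table), table)

summary = pn.net_summary(net, n_genes=35, n_timepoints=11, n_cells=24)
print(f"places (states):        {summary.n_places}")
print(f"transitions (transits): {summary.n_transitions}")
print(f"T/P ratio:              {summary.t_per_p:.2f}")
print(f"minimal T-invariants:   {summary.n_t_invariants}")

analysis = pn.graph_analysis(net)
print(f"source places: {len(analysis.sources)}  sink places: {len(analysis.sinks)}")
print(f"terminal states of stimulated cells: "
      f"{sorted(s for s in analysis.sinks if s > 63)}")

for inv in pn.minimal_t_invariants(net):
    print("cycle:", " -> ".join(f"C{p}" for p in inv.places + (inv.places[0],)))

# A place with many occurrences and a long mean residence run is a
# meta-stable expression state the cells linger in before proceeding.
ann = net.place_annotations.sort_values("relative_stability", ascending=False)
print("\nmost stable states (mean residence run in hours):")
print(ann[["occurrences", "mean_run_length", "relative_stability"]].head(5))
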