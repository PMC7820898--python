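"""Full synthetic round trip: planted Markov chain -> measurements -> net.

A ground-truth chain of expression states is sampled, cells walk on it,
noisy four-replicate measurements are generated, normalized, QC-filtered,
SIMPROF-clustered and reassembled into a Petri net.  Because the truth is
known, we can check that every recovered transit is a real chain edge.
"""

import plasmonet as pn

chain = pn.generate_truth_chain(n_states=10, cycle_fraction=0.2, seed=11)
truth = pn.simulate_trajectories(chain, n_cells=24, n_timepoints=11, seed=12)
panel = pn.PanelSpec()  # 35 genes, sigma_tech 0.43, sigma_bio 0.1
profiles = pn.generate_profiles(chain, panel, seed=13)
expr = pn.generate_expression_table(truth, panel, profiles, seed=14)
print(f"generated {len(expr)} measurements "
      f"({truth.n_cells} cells x 11 h x {len(panel.genes)} genes x 4 replicates)")

normed = pn.normalize_sample_median(expr)
report = pn.replicate_deviations(normed, group="pair")
filtered, report = pn.apply_qc_filters(normed, report)
normed = pn.normalize_gene_geomean(filtered)
print(f"QC kept {len(normed)}/{len(expr)} records; "
      f"excluded plasmodia: {report.excluded_plasmodia or 'none'}")

# the occasional failed RT-PCR (1% of reactions at ~0.1x) can void both
# pairs of a gene; refill such holes with the gene's geometric mean
import numpy as np

matrix = pn.aggregate_measurements(normed)
matrix = matrix.fillna(np.exp(np.log(matrix).mean(axis=0, skipna=True)))
assignment = pn.significant_clusters(
    pn.agglomerate(pn.pairwise_distances(matrix)),
    matrix, alpha=0.05, seed=15, n_expected=199, n_simulated=199,
)
print(f"SIMPROF found {assignment.n_clusters} significant expression states "
      f"(truth uses {len(truth.states())})")

meta = {r.cell: (r.experiment, r.condition) for r in truth}
table = pn.assign_trajectories(assignment.labels, meta)
net = pn.build_net(table)
print(f"recovered net: {len(net.places)} places, "
      f"{len(net.ordinary_transitions())} transitions")

# Map recovered transits back to truth states via the cluster majority
state_of = {(r.cell, t): s for r in truth for t, s in enumerate(r.states)}
votes = {}
for key, label in assignment.labels.items():
    votes.setdefault(label, []).append(state_of[key])
to_truth = {label: max(set(v), key=v.count) for label, v in votes.items()}
recovered = {
    (to_truth[t.pre], to_truth[t.post])
    for t in net.ordinary_transitions()
    if to_truth[t.pre] != to_truth[t.post]
}
spurious = recovered - set(chain.edges)
print(f"recovered {len(recovered & set(chain.edges))} true chain edges, "
      f"{len(spurious)} spurious ones")
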