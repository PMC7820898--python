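"""Visual analytics: classical MDS and discretized kinetics curves.

MDS projects each cell-timepoint expression vector to coordinates whose
pairwise distances approximate the full (log10) Euclidean distances;
the percent of variance per coordinate says how much structure each
axis captures.  Kinetics curves show, per gene, the log10 fold change
of a cell's state profile relative to its 0 h state.
"""

import plasmonet as pn

chain = pn.generate_truth_chain(8, seed=21)
truth = pn.simulate_trajectories(chain, 12, 11, seed=22)
panel = pn.PanelSpec(failed_rate=0.0)
profiles = pn.generate_profiles(chain, panel, seed=23)
expr = pn.generate_expression_table(truth, panel, profiles, seed=24)

normed = pn.normalize_gene_geomean(pn.normalize_sample_median(expr))
matrix = pn.aggregate_measurements(normed)

result = pn.classical_mds(matrix, k=2)
print("MDS percent variance:",
      ", ".join(f"coordinate {i + 1}: {v:.1f}%"
                for i, v in enumerate(result.percent_variance)))
print(result.coordinates.head(4).round(3))

# restrict to the up-regulated genes only (standard gene-subset views)
up = pn.classical_mds(matrix, k=2, gene_subset=panel.subset("up"))
print(f"up-regulated genes only: coordinate 1 carries "
      f"{up.percent_variance[0]:.1f}% of variance")

row = truth.rows[0]
curves = pn.kinetics_curves(row, profiles, genes=["up01", "down01", "ref01"])
print(f"\nkinetics of cell {row.cell} (log10 fold change vs 0 h):")
print(curves.round(2).to_string())
print("\nCurves are stepwise constant while the cell stays in a state;"
      " up-regulated genes climb, down-regulated fall, reference genes"
      " stay near 0.")
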