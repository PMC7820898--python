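"""End-to-end orchestration of the analysis stages.

``run_pipeline`` drives raw (or simulated) measurements through
normalization, replicate QC, SIMPROF clustering, trajectory assembly,
Petri-net construction/analysis and the MDS/kinetics visual analytics,
writing every artifact plus the effective configuration to an output
directory.  Identical config and seed give identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import andl, ordination, petrinet, preprocess, simprof, synthetic, trajectories
from .errors import ArgumentError

log = logging.getLogger("plasmonet")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    fold_limit: float = 2.0
    alpha: float = 0.05
    linkage: str = "average"
    transform: str = "log10"
    n_expected: int = 999
    n_simulated: int = 999
    n_cells: int = 24
    n_timepoints: int = 11
    n_states: int = 20
    weights_policy: str = "weighted"
    gene_subset: str = "all"
    out_dir: str = "plasmonet_out"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )


def run_pipeline(config: PipelineConfig, source: str = "simulate") -> Path:
    """Run every applicable stage; returns the artifact directory.

    ``source`` is ``"simulate"`` (generate synthetic study-design
    data), ``"fixture:table2"`` (the packaged observed trajectories;
    normalization and clustering are skipped since the states are given)
    or the path of an expression-table TSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    config.to_file(out / "config.yaml")

    profiles = None
    panel = synthetic.PanelSpec()
    if source == "fixture:table2":
        table = synthetic.table2_fixture()
        log.info("loaded fixture: %d cells x %d timepoints", table.n_cells, table.n_timepoints)
        trajectories.write_trajectory_table(table, out / "trajectories.tsv")
        n_genes = 35
    else:
        if source == "simulate":
            chain = synthetic.generate_truth_chain(
                config.n_states, seed=config.seed
            )
            truth = synthetic.simulate_trajectories(
                chain, config.n_cells, config.n_timepoints, seed=config.seed + 1
            )
            profiles_truth = synthetic.generate_profiles(
                chain, panel, seed=config.seed + 2
            )
            expr = synthetic.generate_expression_table(
                truth, panel, profiles_truth, seed=config.seed + 3
            )
            trajectories.write_trajectory_table(truth, out / "truth_trajectories.tsv")
        else:
            expr = pd.read_csv(source, sep="\t", comment="#")
        expr.to_csv(out / "expression_raw.tsv", sep="\t", index=False)
        log.info("expression table: %d records", len(expr))

        normed = preprocess.normalize_sample_median(expr)
        report = preprocess.replicate_deviations(normed, group="pair")
        preprocess.deviation_quantiles(report)
        report.quantile_table.to_csv(out / "qc_quantiles.tsv", sep="\t", index=False)
        filtered, report = preprocess.apply_qc_filters(
            normed, report, fold_limit=config.fold_limit
        )
        log.info(
            "QC: dropped %d of %d records; excluded plasmodia: %s",
            len(normed) - len(filtered), len(normed),
            report.excluded_plasmodia or "none",
        )
        normed = preprocess.normalize_gene_geomean(filtered)
        normed.to_csv(out / "expression_normalized.tsv", sep="\t", index=False)

        matrix = preprocess.aggregate_measurements(normed)
        n_holes = int(matrix.isna().to_numpy().sum())
        if n_holes:
            # all four replicates of a gene removed by QC: impute the
            # gene's geometric mean so the design stays complete
            import numpy as np

            gene_gm = np.exp(np.log(matrix).mean(axis=0, skipna=True))
            matrix = matrix.fillna(gene_gm)
            log.info("imputed %d QC holes with per-gene geometric means", n_holes)
        n_genes = matrix.shape[1]
        matrix.to_csv(out / "expression_matrix.tsv", sep="\t")

        distances = simprof.pairwise_distances(matrix, transform=config.transform)
        dendrogram = simprof.agglomerate(distances, method=config.linkage)
        assignment = simprof.significant_clusters(
            dendrogram,
            matrix,
            alpha=config.alpha,
            seed=config.seed,
            n_expected=config.n_expected,
            n_simulated=config.n_simulated,
            transform=config.transform,
        )
        assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        log.info("SIMPROF: %d significant clusters", assignment.n_clusters)
        profiles = simprof.cluster_profiles(assignment, matrix)
        profiles.values.to_csv(out / "cluster_profiles.tsv", sep="\t")
        profiles.log10().to_csv(out / "cluster_profiles_log10.tsv", sep="\t")

        meta = {
            str(c): (str(e), str(d))
            for c, e, d in expr[["cell", "experiment", "condition"]]
            .drop_duplicates()
            .itertuples(index=False)
        }
        meta = {c: meta[c] for c in meta if c in set(matrix.index.get_level_values(0))}
        table = trajectories.assign_trajectories(assignment.labels, meta)
        trajectories.write_trajectory_table(table, out / "trajectories.tsv")

        mds = ordination.classical_mds(matrix, k=2, transform=config.transform)
        with open(out / "mds_coordinates.tsv", "w", encoding="utf-8") as fh:
            pv = ", ".join(f"{v:.2f}%" for v in mds.percent_variance)
            fh.write(f"# percent variance per coordinate: {pv}\n")
            mds.coordinates.to_csv(fh, sep="\t")
        ordination.plot_mds(mds, out / "mds.png")

    net = petrinet.build_net(table)
    net = petrinet.annotate_net(net, table)
    andl.write_andl(net, out / "net.andl")
    andl.write_dot(net, out / "net.dot")
    net.place_annotations.to_csv(out / "place_annotations.tsv", sep="\t")
    invariants = petrinet.minimal_t_invariants(net)
    with open(out / "t_invariants.tsv", "w", encoding="utf-8") as fh:
        fh.write("cycle\n")
        for inv in invariants:
            fh.write("->".join(f"C{p}" for p in inv.places) + "\n")
    summary = petrinet.net_summary(
        net,
        n_genes=n_genes,
        n_timepoints=table.n_timepoints,
        n_cells=table.n_cells,
        n_t_invariants=len(invariants),
    )
    summary.to_frame().to_csv(out / "net_summary.tsv", sep="\t", index=False)
    log.info(
        "net: %d places, %d transitions, %d minimal T-invariants",
        summary.n_places, summary.n_transitions, summary.n_t_invariants,
    )

    if profiles is not None:
        curves = ordination.kinetics_table(table, profiles)
        curves.to_csv(out / "kinetics.tsv", sep="\t", index=False)
    return out
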