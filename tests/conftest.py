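import numpy as np
import pandas as pd
import pytest

import plasmonet as pn
from plasmonet.trajectories import TrajectoryRow, TrajectoryTable


@pytest.fixture(scope="session")
def table2():
    return pn.table2_fixture()


@pytest.fixture(scope="session")
def fixture_net(table2):
    net = pn.build_net(table2)
    return pn.annotate_net(net, table2)


@pytest.fixture()
def branch_cycle_table():
    """The worked construction example: branch at state 2, cycle 1-2-4-1.

    Rows are padded with a trailing self-stay to share one grid; self
    transits create no transitions, so the edge set is unchanged.
    """
    return TrajectoryTable(
        [
            TrajectoryRow("P1", "1", "dark", (1, 2, 3, 3)),
            TrajectoryRow("P2", "1", "dark", (1, 2, 4, 1)),
        ]
    )


@pytest.fixture(scope="session")
def zero_noise_setup():
    """Chain, trajectories, truth profiles and noise-free measurements."""
    chain = pn.generate_truth_chain(8, seed=11)
    traj = pn.simulate_trajectories(chain, n_cells=12, n_timepoints=11, seed=12)
    panel = pn.PanelSpec(sigma_tech=0.0, sigma_bio=0.0, failed_rate=0.0)
    profiles = pn.generate_profiles(chain, panel, seed=13)
    expr = pn.generate_expression_table(traj, panel, profiles, seed=14)
    return chain, traj, panel, profiles, expr


def toy_expression(values_by_measurement, gene_names=None):
    """Long table from {(cell, t, sample, replicate): [v_g, ...]}."""
    records = []
    for (cell, t, sample, rep), values in values_by_measurement.items():
        genes = gene_names or [f"g{i + 1}" for i in range(len(values))]
        for gene, v in zip(genes, values):
            records.append(
                dict(
                    gene=gene,
                    cell=cell,
                    experiment="1",
                    condition="dark",
                    time_h=t,
                    sample=sample,
                    replicate=rep,
                    value=float(v),
                )
            )
    return pd.DataFrame(records)
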