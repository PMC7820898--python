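"""Synthetic single-plasmodium expression time series with known truth.

The generator emulates the study design the analysis assumes: a panel
of 35 genes (10 up-regulated, 10 down-regulated, 4 condition-
independent "pcnA-group" genes, 11 reference genes) measured hourly for
11 time points in 24 giant plasmodial cells, with two biological
samples per cell and time point and two technical RT-PCR replicates
per sample.  Ground truth is a Markov chain of discrete expression
states ("TruthChain"); cells perform random walks on it and every
measurement is the state's profile value times multiplicative
log2-normal biological and technical noise.

The technical noise scale defaults to sigma_tech = 0.43 log2 units,
calibrated so that the analytic 95 % quantile of the x-fold deviation
of one replicate from its pair mean is 1.333:

    r_q = 2 / (1 + 2^(-z_q * sigma * sqrt(2))),  z_0.95 = 1.645.

A packaged fixture transcribes the study's 24 observed single-cell
trajectories (24 cells x 11 hourly states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError
from .simprof import ClusterProfile
from .trajectories import TrajectoryRow, TrajectoryTable, read_trajectory_table

__all__ = [
    "TruthChain",
    "PanelSpec",
    "generate_truth_chain",
    "simulate_trajectories",
    "generate_profiles",
    "generate_expression_table",
    "table2_fixture",
]

EXPRESSION_COLUMNS = [
    "gene",
    "cell",
    "experiment",
    "condition",
    "time_h",
    "sample",
    "replicate",
    "value",
]


@dataclass
class TruthChain:
    """Planted Markov chain of expression states.

    ``edges`` maps ordered state pairs to transition probabilities;
    staying in a state is a separate per-state probability, so edges
    never point from a state to itself.  For each state, self-stay plus
    outgoing edge probabilities sum to one.
    """

    states: set[int]
    edges: dict[tuple[int, int], float]
    self_stay: dict[int, float]
    initial_distribution: dict[int, float]
    condition_label: str = "far_red"

    def __post_init__(self) -> None:
        if not self.states:
            raise ArgumentError("chain must have at least one state")
        for (a, b), p in self.edges.items():
            if a == b:
                raise ArgumentError(f"self edge {a}->{b}; use self_stay instead")
            if not 0.0 <= p <= 1.0:
                raise ArgumentError(f"edge probability out of [0,1]: {p}")
        for s in self.states:
            total = self.self_stay.get(s, 0.0) + sum(
                p for (a, _), p in self.edges.items() if a == s
            )
            if abs(total - 1.0) > 1e-9:
                raise ArgumentError(f"probabilities of state {s} sum to {total}")
        init = sum(self.initial_distribution.values())
        if abs(init - 1.0) > 1e-9:
            raise ArgumentError(f"initial distribution sums to {init}")

    def successors(self, state: int) -> list[tuple[int, float]]:
        return [((b), p) for (a, b), p in self.edges.items() if a == state]


@dataclass
class PanelSpec:
    """The measured gene panel and its noise model.

    ``fold_range`` is the multiplicative span of differential
    regulation (ten- to more than hundred-fold).  ``sigma_tech`` and
    ``sigma_bio`` are log2-scale standard deviations of the technical
    (replicate) and biological (between-sample) noise.  ``failed_rate``
    is the probability that a single RT-PCR reaction fails and reports
    ~0.1x the expected value, producing the low-value tail seen in real
    replicate-deviation histograms; set it to 0 for clean calibration
    runs.
    """

    n_up: int = 10
    n_down: int = 10
    n_pcna: int = 4
    n_reference: int = 11
    fold_range: tuple[float, float] = (10.0, 100.0)
    sigma_tech: float = 0.43
    sigma_bio: float = 0.1
    failed_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.fold_range[0] <= 1.0 or self.fold_range[1] < self.fold_range[0]:
            raise ArgumentError(f"invalid fold_range {self.fold_range}")
        if self.sigma_tech < 0 or self.sigma_bio < 0:
            raise ArgumentError("sigma values must be >= 0")
        if not 0.0 <= self.failed_rate < 1.0:
            raise ArgumentError("failed_rate must be in [0, 1)")

    @property
    def genes(self) -> list[str]:
        return (
            [f"up{i:02d}" for i in range(1, self.n_up + 1)]
            + [f"down{i:02d}" for i in range(1, self.n_down + 1)]
            + [f"pcna{i:02d}" for i in range(1, self.n_pcna + 1)]
            + [f"ref{i:02d}" for i in range(1, self.n_reference + 1)]
        )

    @property
    def classes(self) -> dict[str, str]:
        out = {}
        for g in self.genes:
            out[g] = (
                "up"
                if g.startswith("up")
                else "down"
                if g.startswith("down")
                else "pcnA_group"
                if g.startswith("pcna")
                else "reference"
            )
        return out

    def subset(self, which: str) -> list[str]:
        """Gene names for the standard analysis subsets."""
        cls = self.classes
        selectors = {
            "all": lambda c: True,
            "up": lambda c: c == "up",
            "down": lambda c: c == "down",
            "updown": lambda c: c in ("up", "down"),
            "pcna": lambda c: c == "pcnA_group",
        }
        if which not in selectors:
            raise ArgumentError(f"unknown gene subset {which!r}")
        return [g for g in self.genes if selectors[which](cls[g])]


def generate_truth_chain(
    n_states: int,
    branching: float = 1.6,
    cycle_fraction: float = 0.15,
    seed: int = 0,
    condition_label: str = "far_red",
    self_stay: float = 0.4,
) -> TruthChain:
    """Random connected state chain with tunable branching and cyclicity.

    States 1..n are ordered along a backbone 1->2->...->n (guaranteeing
    reachability from state 1); extra forward edges raise the mean
    out-degree toward ``branching`` and a ``cycle_fraction`` share of
    states gains one back edge, creating elementary cycles.  With
    ``cycle_fraction=0`` every edge points forward, so the chain is
    acyclic by construction.
    """
    if n_states < 1:
        raise ArgumentError(f"n_states must be >= 1, got {n_states}")
    if not 0.0 <= cycle_fraction <= 1.0:
        raise ArgumentError("cycle_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    states = set(range(1, n_states + 1))
    if n_states == 1:
        return TruthChain(states, {}, {1: 1.0}, {1: 1.0}, condition_label)

    successors: dict[int, set[int]] = {s: set() for s in states}
    for s in range(1, n_states):
        successors[s].add(s + 1)
    forward = [
        (i, j) for i in range(1, n_states) for j in range(i + 2, n_states + 1)
    ]
    n_extra = min(len(forward), max(0, round((branching - 1.0) * (n_states - 1))))
    if n_extra:
        for k in rng.choice(len(forward), size=n_extra, replace=False):
            i, j = forward[k]
            successors[i].add(j)
    back = [(i, j) for i in range(2, n_states + 1) for j in range(1, i)]
    n_back = min(len(back), round(cycle_fraction * (n_states - 1)))
    if n_back:
        for k in rng.choice(len(back), size=n_back, replace=False):
            i, j = back[k]
            successors[i].add(j)

    edges: dict[tuple[int, int], float] = {}
    stay: dict[int, float] = {}
    for s in states:
        succ = sorted(successors[s])
        if not succ:
            stay[s] = 1.0
            continue
        stay[s] = self_stay
        weights = rng.dirichlet(np.ones(len(succ)) * 2.0)
        mass = 1.0 - self_stay
        probs = weights * mass
        # make the row sum exactly 1 despite float rounding
        probs[-1] = mass - probs[:-1].sum()
        for t, p in zip(succ, probs):
            edges[(s, t)] = float(p)

    n_initial = max(1, n_states // 3)
    init_weights = rng.dirichlet(np.ones(n_initial) * 2.0)
    init_weights[-1] = 1.0 - init_weights[:-1].sum()
    initial = {s + 1: float(w) for s, w in enumerate(init_weights)}
    return TruthChain(states, edges, stay, initial, condition_label)


def simulate_trajectories(
    chain: TruthChain,
    n_cells: int = 24,
    n_timepoints: int = 11,
    seed: int = 0,
) -> TrajectoryTable:
    """Random walks of ``n_cells`` cells on the chain, one state per hour.

    Cells are named P1..Pn and split half/half over experiment batches
    "1" and "2"; every consecutive change of state follows an edge of
    the chain.
    """
    if n_timepoints < 1:
        raise ArgumentError("n_timepoints must be >= 1")
    if n_cells < 1:
        raise ArgumentError("n_cells must be >= 1")
    if not chain.states:
        raise ArgumentError("empty chain")
    rng = np.random.default_rng(seed)
    init_states = sorted(chain.initial_distribution)
    init_probs = np.array([chain.initial_distribution[s] for s in init_states])
    rows = []
    for i in range(n_cells):
        state = int(rng.choice(init_states, p=init_probs))
        seq = [state]
        for _ in range(n_timepoints - 1):
            succ = chain.successors(state)
            if succ and rng.random() >= chain.self_stay.get(state, 0.0):
                targets = [t for t, _ in succ]
                probs = np.array([p for _, p in succ])
                probs = probs / probs.sum()
                state = int(rng.choice(targets, p=probs))
            seq.append(state)
        experiment = "1" if i < n_cells / 2 else "2"
        rows.append(
            TrajectoryRow(
                f"P{i + 1}", experiment, chain.condition_label, tuple(seq)
            )
        )
    return TrajectoryTable(rows)


def generate_profiles(
    chain: TruthChain, panel: PanelSpec, seed: int = 0
) -> ClusterProfile:
    """Ground-truth expression profile (per gene) of every chain state.

    Up- and down-regulated genes drift monotonically along the chain's
    backbone order when the chain models a far-red stimulated cell
    (regulation spans a fold factor drawn log-uniformly from
    ``panel.fold_range``); in dark-control chains, and always for the
    pcnA-group, expression performs a condition-independent random walk
    in log2 space.  Reference genes stay at their baseline.
    """
    rng = np.random.default_rng(seed)
    states = sorted(chain.states)
    n = len(states)
    progress = (
        {s: 0.0 for s in states}
        if n == 1
        else {s: k / (n - 1) for k, s in enumerate(states)}
    )
    genes = panel.genes
    classes = panel.classes
    lo, hi = np.log(panel.fold_range[0]), np.log(panel.fold_range[1])
    data = np.empty((n, len(genes)))
    directed = chain.condition_label == "far_red"
    for j, gene in enumerate(genes):
        baseline = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        cls = classes[gene]
        if cls in ("up", "down") and directed:
            fold = float(np.exp(rng.uniform(lo, hi)))
            sign = 1.0 if cls == "up" else -1.0
            jitter = rng.normal(0.0, 0.15, size=n)
            col = baseline * fold ** (
                sign * np.array([progress[s] for s in states])
            ) * np.exp2(jitter)
        elif cls == "reference":
            col = np.full(n, baseline)
        else:  # pcnA-group always, up/down in dark controls
            walk = np.cumsum(rng.normal(0.0, 0.5, size=n))
            col = baseline * np.exp2(walk - walk[0])
        data[:, j] = col
    frame = pd.DataFrame(data, index=states, columns=genes)
    frame.index.name = "cluster"
    return ClusterProfile(frame, pd.Series(1, index=states, name="n"))


def generate_expression_table(
    trajectories: TrajectoryTable,
    panel: PanelSpec,
    profiles: ClusterProfile,
    seed: int = 0,
    failed_rate: float | None = None,
) -> pd.DataFrame:
    """Noisy measurement table for a set of trajectories.

    Every cell-timepoint is sampled twice (biological samples 1 and 2)
    and every sample is measured twice (technical replicates 1 and 2):

        value = profile[state, gene] * 2^N(0, sigma_bio)   per sample
                                     * 2^N(0, sigma_tech)  per replicate

    ``failed_rate`` overrides ``panel.failed_rate`` when given; a
    failed reaction multiplies a single replicate by 0.1.
    """
    missing = trajectories.states() - set(profiles.clusters)
    if missing:
        raise DataError(f"no ground-truth profile for states {sorted(missing)}")
    if (profiles.values.to_numpy() <= 0).any():
        raise DataError("profiles must be strictly positive")
    rate = panel.failed_rate if failed_rate is None else failed_rate
    rng = np.random.default_rng(seed)
    genes = profiles.genes
    n_genes = len(genes)
    cols: dict[str, list] = {c: [] for c in EXPRESSION_COLUMNS}
    for row in trajectories:
        for t, state in enumerate(row.states):
            base = profiles.profile(state).to_numpy()
            for sample in (1, 2):
                bio = np.exp2(rng.normal(0.0, panel.sigma_bio, size=n_genes))
                for replicate in (1, 2):
                    tech = np.exp2(rng.normal(0.0, panel.sigma_tech, size=n_genes))
                    values = base * bio * tech
                    if rate > 0.0:
                        failed = rng.random(n_genes) < rate
                        values = np.where(failed, values * 0.1, values)
                    cols["gene"].append(genes)
                    cols["cell"].append(row.cell)
                    cols["experiment"].append(row.experiment)
                    cols["condition"].append(row.condition)
                    cols["time_h"].append(t)
                    cols["sample"].append(sample)
                    cols["replicate"].append(replicate)
                    cols["value"].append(values)
    return pd.DataFrame(
        {
            "gene": np.concatenate(cols["gene"]),
            "cell": np.repeat(cols["cell"], n_genes),
            "experiment": np.repeat(cols["experiment"], n_genes),
            "condition": np.repeat(cols["condition"], n_genes),
            "time_h": np.repeat(cols["time_h"], n_genes),
            "sample": np.repeat(cols["sample"], n_genes),
            "replicate": np.repeat(cols["replicate"], n_genes),
            "value": np.concatenate(cols["value"]),
        }
    )


def table2_fixture() -> TrajectoryTable:
    """The packaged 24-cell x 11-timepoint observed trajectory table."""
    path = resources.files("plasmonet") / "data" / "table2_trajectories.tsv"
    with resources.as_file(path) as p:
        return read_trajectory_table(p)
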