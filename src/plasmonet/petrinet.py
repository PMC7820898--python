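"""Waddington-landscape state-machine Petri nets.

Each significant gene-expression state is a *place*; each observed
temporal transit between two different states is a *transition* with
exactly one pre-place and one post-place (arc weights all 1), so the
net is a state machine: with a single token it is isomorphic to its
own reachability graph, and — stochastic firing assumed — represents
the Markov chain of states the cells pass through.

An auxiliary start place C0 (ID 0) holds the initial token; *immediate
transitions* C0 -> s distribute it over the observed initial states
with weights equal to how many cells started in each state.  Self
transits (a cell staying in its state between samples) create no
transition; they enter the residence-time statistics instead.

Minimal T-invariants of a state machine are exactly the elementary
directed cycles of its place graph, enumerated here by Johnson's
algorithm with a configurable cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ArgumentError, DataError, PlasmonetError
from .trajectories import TrajectoryTable

__all__ = [
    "C0",
    "Transition",
    "StateNet",
    "TInvariant",
    "GraphAnalysis",
    "NetSummary",
    "build_net",
    "annotate_net",
    "residence_stability",
    "graph_analysis",
    "minimal_t_invariants",
    "net_summary",
    "accepts",
    "simulate_token_game",
    "reachability_graph",
]

C0 = 0  # auxiliary start place


@dataclass
class Transition:
    pre: int
    post: int
    immediate: bool = False
    count: int = 0
    provenance: frozenset[tuple[str, str]] = frozenset()
    weight: float = 1.0

    @property
    def id(self) -> str:
        return f"t_C{self.pre}_C{self.post}"


@dataclass
class StateNet:
    """Single-token state-machine Petri net."""

    places: set[int] = field(default_factory=set)  # state IDs, excludes C0
    transitions: dict[tuple[int, int], Transition] = field(default_factory=dict)
    place_annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Structural state-machine invariants."""
        if C0 in self.places:
            raise ArgumentError("C0 is implicit and must not appear in places")
        for (pre, post), t in self.transitions.items():
            if (pre, post) != (t.pre, t.post):
                raise ArgumentError(f"transition {t.id} filed under wrong key")
            if pre == post:
                raise ArgumentError(f"self-loop transition C{pre}->C{post}")
            if t.immediate != (pre == C0):
                raise ArgumentError(
                    f"transition {t.id}: immediate iff pre-place is C0"
                )
            if post == C0:
                raise ArgumentError("no transition may target C0")
            for place in (pre, post):
                if place != C0 and place not in self.places:
                    raise ArgumentError(f"transition {t.id} uses unknown place {place}")

    # -- views ---------------------------------------------------------
    def ordinary_transitions(self) -> list[Transition]:
        return [t for t in self.transitions.values() if not t.immediate]

    def immediate_transitions(self) -> list[Transition]:
        return [t for t in self.transitions.values() if t.immediate]

    def initial_places(self) -> set[int]:
        return {t.post for t in self.immediate_transitions()}

    def ordinary_graph(self) -> nx.DiGraph:
        """Place graph over ordinary transitions only (C0 excluded)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.places)
        g.add_edges_from(
            (t.pre, t.post, {"count": t.count, "weight": t.weight})
            for t in self.ordinary_transitions()
        )
        return g

    def full_graph(self) -> nx.DiGraph:
        g = self.ordinary_graph()
        g.add_node(C0)
        g.add_edges_from((C0, t.post) for t in self.immediate_transitions())
        return g

    def __eq__(self, other: object) -> bool:
        """Structural equality: places and (pre, post, immediate, weight)."""
        if not isinstance(other, StateNet):
            return NotImplemented
        mine = {k: (t.immediate, round(t.weight, 9)) for k, t in self.transitions.items()}
        theirs = {
            k: (t.immediate, round(t.weight, 9)) for k, t in other.transitions.items()
        }
        return self.places == other.places and mine == theirs


@dataclass(frozen=True)
class TInvariant:
    """Minimal T-invariant: an elementary cycle of transitions.

    ``places`` is the cycle in canonical rotation (smallest place ID
    first); firing the ``transitions`` in order returns the token to
    its starting place.
    """

    places: tuple[int, ...]

    @property
    def transitions(self) -> tuple[tuple[int, int], ...]:
        cycle = self.places + (self.places[0],)
        return tuple(zip(cycle[:-1], cycle[1:]))

    def __len__(self) -> int:
        return len(self.places)


@dataclass
class GraphAnalysis:
    sources: set[int]
    sinks: set[int]
    weak_components: list[frozenset[int]]
    strong_components: list[frozenset[int]]

    @property
    def n_components(self) -> int:
        return len(self.weak_components)


@dataclass
class NetSummary:
    """Net metrics in the layout of the study's summary table."""

    n_places: int
    n_transitions: int
    n_t_invariants: int
    n_genes: int
    n_timepoints: int
    n_cells: int
    n_sources: int
    n_sinks: int
    n_components: int

    @property
    def p_per_gene(self) -> float:
        return self.n_places / self.n_genes

    @property
    def t_per_gene(self) -> float:
        return self.n_transitions / self.n_genes

    @property
    def t_per_p(self) -> float:
        return self.n_transitions / self.n_places if self.n_places else 0.0

    @property
    def p_per_gtc(self) -> float:
        return self.n_places / (self.n_genes * self.n_timepoints * self.n_cells)

    @property
    def t_per_gtc(self) -> float:
        return self.n_transitions / (self.n_genes * self.n_timepoints * self.n_cells)

    @property
    def tinv_per_gene(self) -> float:
        return self.n_t_invariants / self.n_genes

    def to_frame(self) -> pd.DataFrame:
        """Summary rows named and rounded like the printed table."""
        rows = [
            ("Genes", self.n_genes, self.n_genes),
            ("Places", self.n_places, self.n_places),
            ("Transitions", self.n_transitions, self.n_transitions),
            ("P/Gene", self.p_per_gene, round(self.p_per_gene, 1)),
            ("T/Gene", self.t_per_gene, round(self.t_per_gene, 1)),
            ("Time points", self.n_timepoints, self.n_timepoints),
            ("Cells", self.n_cells, self.n_cells),
            ("P/(Genes x tps x cells)", self.p_per_gtc, round(self.p_per_gtc, 3)),
            ("T/(Genes x tps x cells)", self.t_per_gtc, round(self.t_per_gtc, 3)),
            ("T/P", self.t_per_p, round(self.t_per_p, 2)),
            ("T-Inv", self.n_t_invariants, self.n_t_invariants),
            ("T-Inv/Gene", self.tinv_per_gene, round(self.tinv_per_gene, 2)),
            ("Sources", self.n_sources, self.n_sources),
            ("Sinks", self.n_sinks, self.n_sinks),
            ("Components", self.n_components, self.n_components),
        ]
        return pd.DataFrame(rows, columns=["metric", "value", "printed"])


# ----------------------------------------------------------------------
# construction


def build_net(trajectories: TrajectoryTable) -> StateNet:
    """Assemble the state machine from a set of trajectories.

    Places are the distinct states; one ordinary transition per
    distinct ordered pair of consecutive *differing* states anywhere in
    the table (multiplicity recorded in ``count``, originating
    (experiment, condition) pairs in ``provenance``); one immediate
    transition C0 -> s per distinct initial state, weighted by the
    number of cells starting in s.
    """
    if len(trajectories) == 0:
        raise ArgumentError("cannot build a net from an empty trajectory table")
    places: set[int] = set()
    transitions: dict[tuple[int, int], Transition] = {}
    counts: dict[tuple[int, int], int] = {}
    prov: dict[tuple[int, int], set[tuple[str, str]]] = {}
    initial_counts: dict[int, int] = {}
    for row in trajectories:
        places.update(row.states)
        initial_counts[row.states[0]] = initial_counts.get(row.states[0], 0) + 1
        for a, b in zip(row.states, row.states[1:]):
            if a == b:
                continue
            counts[(a, b)] = counts.get((a, b), 0) + 1
            prov.setdefault((a, b), set()).add((row.experiment, row.condition))
    for (a, b), n in sorted(counts.items()):
        transitions[(a, b)] = Transition(
            a, b, immediate=False, count=n, provenance=frozenset(prov[(a, b)]),
            weight=float(n),
        )
    for s, n in sorted(initial_counts.items()):
        transitions[(C0, s)] = Transition(
            C0, s, immediate=True, count=n, provenance=frozenset(), weight=float(n)
        )
    return StateNet(places=places, transitions=transitions)


def annotate_net(net: StateNet, trajectories: TrajectoryTable) -> StateNet:
    """Attach place frequencies, stabilities and source/sink flags.

    Place ``relative_frequency`` is the share of all cell-timepoints
    spent in the state; transition counts and provenance are recomputed
    from the table and must agree with the net.
    """
    rebuilt = build_net(trajectories)
    if rebuilt != net:
        raise DataError("net was not built from these trajectories")
    for key, t in rebuilt.transitions.items():
        existing = net.transitions[key]
        existing.count = t.count
        existing.provenance = t.provenance
    total = trajectories.n_cells * trajectories.n_timepoints
    occupancy = {p: 0 for p in net.places}
    for row in trajectories:
        for s in row.states:
            occupancy[s] += 1
    stability = residence_stability(net, trajectories)
    analysis = graph_analysis(net)
    ann = pd.DataFrame(
        {
            "place": sorted(net.places),
            "occurrences": [occupancy[p] for p in sorted(net.places)],
            "relative_frequency": [occupancy[p] / total for p in sorted(net.places)],
        }
    ).set_index("place")
    ann["mean_run_length"] = stability["mean_run_length"]
    ann["relative_stability"] = stability["relative_stability"]
    ann["is_source"] = [p in analysis.sources for p in ann.index]
    ann["is_sink"] = [p in analysis.sinks for p in ann.index]
    net.place_annotations = ann
    return net


def residence_stability(
    net: StateNet, trajectories: TrajectoryTable
) -> pd.DataFrame:
    """Mean residence-run length per state and its relative stability.

    A run is a maximal block of consecutive time points a cell spends
    in one state; runs truncated by the start or end of the series
    count at their observed length.  ``relative_stability`` divides by
    the largest mean run length, so it lies in (0, 1].
    """
    runs: dict[int, list[int]] = {p: [] for p in net.places}
    seen: set[int] = set()
    for row in trajectories:
        for state, group in itertools.groupby(row.states):
            length = len(list(group))
            if state not in runs:
                raise DataError(f"trajectory state {state} absent from net")
            runs[state].append(length)
            seen.add(state)
    missing = net.places - seen
    if missing:
        raise DataError(f"net places never occur in trajectories: {sorted(missing)}")
    mean_runs = {p: float(np.mean(r)) for p, r in runs.items()}
    top = max(mean_runs.values())
    frame = pd.DataFrame(
        {
            "place": sorted(net.places),
            "mean_run_length": [mean_runs[p] for p in sorted(net.places)],
        }
    ).set_index("place")
    frame["relative_stability"] = frame["mean_run_length"] / top
    return frame


# ----------------------------------------------------------------------
# analysis


def graph_analysis(net: StateNet) -> GraphAnalysis:
    """Sources, sinks and components of the ordinary place graph.

    Computed with C0 and its immediate transitions excluded: a source
    is a place no ordinary transition enters, a sink is a place no
    ordinary transition leaves (a terminal expression state).
    """
    g = net.ordinary_graph()
    sources = {p for p in g if g.in_degree(p) == 0}
    sinks = {p for p in g if g.out_degree(p) == 0}
    weak = sorted(
        (frozenset(c) for c in nx.weakly_connected_components(g)), key=min
    )
    strong = sorted(
        (frozenset(c) for c in nx.strongly_connected_components(g)), key=min
    )
    return GraphAnalysis(sources, sinks, weak, strong)


def minimal_t_invariants(net: StateNet, cap: int = 10**6) -> list[TInvariant]:
    """All minimal T-invariants (elementary cycles) of the net.

    In a state machine every elementary directed cycle of the place
    graph — no repeated transitions, no repeated intermediate places —
    is a minimal T-invariant, so complete enumeration of the cycles
    (Johnson's algorithm, restricted to nontrivial strongly connected
    components) enumerates them all.  Cycles are canonically rotated to
    start at their smallest place and returned sorted by (length,
    place sequence).
    """
    g = net.ordinary_graph()
    invariants = []
    for cycle in nx.simple_cycles(g):
        k = cycle.index(min(cycle))
        canonical = tuple(cycle[k:] + cycle[:k])
        invariants.append(TInvariant(canonical))
        if len(invariants) > cap:
            raise PlasmonetError(
                f"elementary-cycle enumeration exceeded cap of {cap}"
            )
    invariants.sort(key=lambda inv: (len(inv), inv.places))
    return invariants


def net_summary(
    net: StateNet,
    n_genes: int,
    n_timepoints: int,
    n_cells: int,
    n_t_invariants: int | None = None,
) -> NetSummary:
    """Summary metrics; counts exclude C0 and immediate transitions."""
    if min(n_genes, n_timepoints, n_cells) <= 0:
        raise ArgumentError("gene/timepoint/cell counts must be positive")
    if n_t_invariants is None:
        n_t_invariants = len(minimal_t_invariants(net))
    analysis = graph_analysis(net)
    return NetSummary(
        n_places=len(net.places),
        n_transitions=len(net.ordinary_transitions()),
        n_t_invariants=n_t_invariants,
        n_genes=n_genes,
        n_timepoints=n_timepoints,
        n_cells=n_cells,
        n_sources=len(analysis.sources),
        n_sinks=len(analysis.sinks),
        n_components=analysis.n_components,
    )


# ----------------------------------------------------------------------
# semantics


def accepts(net: StateNet, trajectory: tuple[int, ...] | list[int]) -> bool:
    """Whether the net can replay the trajectory from C0.

    True iff the initial state is reachable by an immediate transition
    and every consecutive differing pair is an ordinary transition.
    The empty trajectory is vacuously accepted.
    """
    seq = list(trajectory)
    if not seq:
        return True
    if (C0, seq[0]) not in net.transitions:
        return False
    for a, b in zip(seq, seq[1:]):
        if a == b:
            continue
        t = net.transitions.get((a, b))
        if t is None or t.immediate:
            return False
    return True


def simulate_token_game(
    net: StateNet,
    n_steps: int = 50,
    seed: int = 0,
    policy: str = "uniform",
) -> list[int]:
    """Play the token game; returns the sequence of visited places.

    The run starts by firing one immediate transition (uniformly under
    ``policy='uniform'``, else proportionally to how many cells started
    in each state) and then repeatedly fires one enabled
    post-transition of the token's place (uniform, or proportional to
    observed transit counts under ``'weighted'``).  It stops at a sink
    place or after ``n_steps`` firings.  Exactly one token exists at
    every step — transitions have one pre- and one post-place each.
    """
    if policy not in ("uniform", "weighted"):
        raise ArgumentError(f"policy must be 'uniform' or 'weighted', got {policy!r}")
    immediates = sorted(net.immediate_transitions(), key=lambda t: t.post)
    if not immediates:
        raise ArgumentError("net has no immediate transitions to start from")
    rng = np.random.default_rng(seed)

    def _fire(options: list[Transition]) -> Transition:
        if policy == "weighted":
            w = np.array([max(t.count, 1) for t in options], dtype=float)
            return options[int(rng.choice(len(options), p=w / w.sum()))]
        return options[int(rng.integers(len(options)))]

    marking = _fire(immediates).post
    sequence = [marking]
    successors: dict[int, list[Transition]] = {}
    for t in net.ordinary_transitions():
        successors.setdefault(t.pre, []).append(t)
    for options in successors.values():
        options.sort(key=lambda t: t.post)
    for _ in range(n_steps):
        options = successors.get(marking)
        if not options:  # sink place: no enabled post-transition
            break
        marking = _fire(options).post
        sequence.append(marking)
    return sequence


def reachability_graph(net: StateNet) -> nx.DiGraph:
    """Graph of reachable markings of the single-token net.

    A marking is identified by the place holding the token; the initial
    marking has it on C0.  For a state machine this graph is isomorphic
    to the net's own place/transit graph rooted at C0 — the Markov
    chain of states.
    """
    g = nx.DiGraph()
    g.add_node(C0)
    frontier = [C0]
    while frontier:
        marking = frontier.pop()
        for (pre, post), t in net.transitions.items():
            if pre != marking:
                continue
            if post not in g:
                g.add_node(post)
                frontier.append(post)
            g.add_edge(pre, post)
    return g
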