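import itertools

import networkx as nx
import numpy as np
import pytest

import plasmonet as pn
from plasmonet.errors import ArgumentError, DataError
from plasmonet.petrinet import C0
from plasmonet.trajectories import TrajectoryRow, TrajectoryTable

from .oracles import brute_force_elementary_cycles


def net_from(*seqs, condition="dark"):
    # pad with trailing self-stays to a shared grid; self transits add
    # no transitions, so the edge set is exactly the listed transits
    length = max(len(s) for s in seqs)
    rows = [
        TrajectoryRow(
            f"P{i + 1}", "1", condition, tuple(s) + (s[-1],) * (length - len(s))
        )
        for i, s in enumerate(seqs)
    ]
    return pn.build_net(TrajectoryTable(rows))


class TestBuildNet:
    def test_constant_trajectory(self):
        net = net_from([5, 5, 5])
        assert net.places == {5}
        assert net.ordinary_transitions() == []
        assert len(net.immediate_transitions()) == 1

    def test_branch_and_cycle(self, branch_cycle_table):
        net = pn.build_net(branch_cycle_table)
        assert net.places == {1, 2, 3, 4}
        post_of_2 = [t for t in net.ordinary_transitions() if t.pre == 2]
        assert {t.post for t in post_of_2} == {3, 4}  # free-choice conflict
        assert (4, 1) in net.transitions
        assert len(pn.minimal_t_invariants(net)) == 1

    def test_fixture_counts(self, fixture_net):
        assert len(fixture_net.places) == 111
        assert len(fixture_net.ordinary_transitions()) == 159
        assert len(fixture_net.immediate_transitions()) == 20

    def test_self_transits_make_no_transition(self):
        net = net_from([1, 1, 2, 2, 1])
        assert set(net.transitions) == {(1, 2), (2, 1), (C0, 1)}

    def test_empty_table_rejected(self):
        with pytest.raises(ArgumentError):
            pn.build_net(TrajectoryTable([]))

    def test_deterministic(self, table2):
        assert pn.build_net(table2) == pn.build_net(table2)


class TestAnnotations:
    def test_state_frequency(self, fixture_net):
        ann = fixture_net.place_annotations
        assert ann.loc[1, "occurrences"] == 2  # final state of P6 and P8 only
        assert ann.loc[1, "relative_frequency"] == pytest.approx(2 / 264)

    def test_transit_occurrences_counting_identity(self, table2, fixture_net):
        # every trajectory contributes L-1 consecutive pairs, split between
        # genuine transits and self-stays
        n_pairs = table2.n_cells * (table2.n_timepoints - 1)
        n_self = sum(
            1
            for row in table2
            for a, b in zip(row.states, row.states[1:])
            if a == b
        )
        total_transits = sum(t.count for t in fixture_net.ordinary_transitions())
        assert n_pairs == 240
        assert total_transits + n_self == n_pairs

    def test_frequencies_sum_to_one(self, fixture_net):
        total = fixture_net.place_annotations["relative_frequency"].sum()
        assert total == pytest.approx(1.0)

    def test_provenance_tracks_batches(self, fixture_net):
        t = fixture_net.transitions[(60, 56)]  # P1 (experiment 1, dark) only
        assert t.provenance == frozenset({("1", "dark")})


class TestResidenceStability:
    def test_state_20_run(self, fixture_net, table2):
        stab = pn.residence_stability(fixture_net, table2)
        assert stab.loc[20, "mean_run_length"] == 3.0  # P19 stays 3 h

    def test_isolated_occurrences(self):
        net = net_from([1, 2, 1, 2, 1])
        table = TrajectoryTable([TrajectoryRow("P1", "1", "dark", (1, 2, 1, 2, 1))])
        stab = pn.residence_stability(net, table)
        assert stab.loc[1, "mean_run_length"] == 1.0
        assert stab.loc[2, "mean_run_length"] == 1.0

    def test_constant_trajectory(self):
        table = TrajectoryTable([TrajectoryRow("P1", "1", "dark", (5, 5, 5))])
        net = pn.build_net(table)
        stab = pn.residence_stability(net, table)
        assert stab.loc[5, "mean_run_length"] == 3.0
        assert stab.loc[5, "relative_stability"] == 1.0

    def test_relative_stability_in_unit_interval(self, fixture_net, table2):
        stab = pn.residence_stability(fixture_net, table2)
        assert ((stab["relative_stability"] > 0) & (stab["relative_stability"] <= 1)).all()


class TestGraphAnalysis:
    def test_linear_path(self):
        ga = pn.graph_analysis(net_from([1, 2, 3]))
        assert ga.sources == {1}
        assert ga.sinks == {3}
        assert ga.n_components == 1

    def test_dark_controls_form_three_components(self, table2):
        net = pn.build_net(table2.subset(condition="dark"))
        assert pn.graph_analysis(net).n_components == 3

    def test_far_red_terminal_states(self, fixture_net, table2):
        sinks = pn.graph_analysis(fixture_net).sinks
        far_red_states = set(
            itertools.chain.from_iterable(
                r.states for r in table2.subset(condition="far_red")
            )
        )
        assert sinks & far_red_states == {71, 76, 77, 78, 79, 95}


class TestTInvariants:
    def test_two_cycle(self):
        net = net_from([1, 2, 1])
        invs = pn.minimal_t_invariants(net)
        assert len(invs) == 1
        assert invs[0].places == (1, 2)
        assert invs[0].transitions == ((1, 2), (2, 1))

    def test_complete_digraph_on_three_nodes(self):
        # all six arcs among three states: three 2-cycles and two 3-cycles
        net = net_from([1, 2, 1, 3, 1], [2, 3, 2], [1, 3, 1], [3, 1, 2, 3])
        g = net.ordinary_graph()
        assert g.number_of_edges() == 6
        invs = pn.minimal_t_invariants(net)
        assert len(invs) == 5
        oracle = brute_force_elementary_cycles(set(g.edges))
        assert sorted((len(i), i.places) for i in invs) == [
            (len(c), c) for c in oracle
        ]

    def test_agrees_with_brute_force_on_random_small_nets(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(3, 13))
            density = rng.uniform(0.1, 0.45)
            edges = {
                (int(a), int(b))
                for a in range(1, n + 1)
                for b in range(1, n + 1)
                if a != b and rng.random() < density
            }
            if not edges:
                continue
            transitions = {
                e: pn.Transition(e[0], e[1], weight=1.0) for e in edges
            }
            places = {p for e in edges for p in e}
            transitions[(C0, min(places))] = pn.Transition(
                C0, min(places), immediate=True, weight=1.0
            )
            net = pn.StateNet(places=places, transitions=transitions)
            invs = pn.minimal_t_invariants(net)
            oracle = brute_force_elementary_cycles(edges)
            assert sorted((len(i), i.places) for i in invs) == [
                (len(c), c) for c in oracle
            ], f"trial {trial}"

    def test_fixture_count_is_reported(self, fixture_net):
        # the enumerated count for the packaged data; reported, by design,
        # rather than asserted against any external tally
        invs = pn.minimal_t_invariants(fixture_net)
        assert isinstance(len(invs), int)
        assert all(len(set(i.places)) == len(i.places) for i in invs)

    def test_cap_enforced(self):
        net = net_from([1, 2, 1, 3, 1, 4, 1], [2, 3, 2, 4, 2], [3, 4, 3, 1, 2])
        with pytest.raises(pn.PlasmonetError):
            pn.minimal_t_invariants(net, cap=1)


class TestNetSummary:
    def test_fixture_ratios(self, fixture_net):
        s = pn.net_summary(fixture_net, n_genes=35, n_timepoints=11, n_cells=24)
        assert round(s.t_per_p, 2) == 1.43
        assert round(s.p_per_gene, 1) == 3.2
        assert round(s.t_per_gene, 1) == 4.5
        assert round(s.p_per_gtc, 3) == 0.012
        assert round(s.t_per_gtc, 3) == 0.017

    def test_single_state_net(self):
        net = net_from([5, 5, 5])
        s = pn.net_summary(net, n_genes=3, n_timepoints=3, n_cells=1)
        assert s.n_places == 1
        assert s.n_transitions == 0
        assert s.t_per_p == 0.0

    def test_zero_denominator_rejected(self, fixture_net):
        with pytest.raises(ArgumentError):
            pn.net_summary(fixture_net, n_genes=0, n_timepoints=11, n_cells=24)

    def test_ratios_recomputable_from_counts(self, fixture_net):
        s = pn.net_summary(fixture_net, 35, 11, 24)
        frame = s.to_frame().set_index("metric")
        assert frame.loc["T/P", "value"] == pytest.approx(
            frame.loc["Transitions", "value"] / frame.loc["Places", "value"]
        )


class TestAccepts:
    def test_building_trajectories_are_accepted(self, fixture_net, table2):
        assert all(pn.accepts(fixture_net, r.states) for r in table2)

    def test_membership(self, fixture_net):
        assert pn.accepts(fixture_net, [60, 56, 59])
        assert not pn.accepts(fixture_net, [60, 59, 56])

    def test_empty_is_vacuously_true(self, fixture_net):
        assert pn.accepts(fixture_net, [])

    def test_unknown_start_rejected(self, fixture_net):
        assert not pn.accepts(fixture_net, [999])


class TestTokenGame:
    def test_no_choice_net_is_deterministic(self):
        net = net_from([1, 2, 3])
        for seed in range(5):
            assert pn.simulate_token_game(net, 10, seed=seed) == [1, 2, 3]

    def test_uniform_branching_probability(self):
        net = net_from([1, 2, 2], [1, 3, 3])
        hits = sum(
            pn.simulate_token_game(net, 1, seed=s)[-1] == 2 for s in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_emitted_sequences_are_accepted(self, fixture_net):
        for seed in range(25):
            seq = pn.simulate_token_game(fixture_net, 30, seed=seed, policy="weighted")
            assert pn.accepts(fixture_net, seq)

    def test_stops_at_sink(self):
        net = net_from([1, 2, 3])
        seq = pn.simulate_token_game(net, 1000, seed=0)
        assert seq[-1] == 3 and len(seq) == 3


class TestStructuralInvariants:
    def test_state_machine_property_everywhere(self, fixture_net, branch_cycle_table):
        # validate() checks one pre-place, one post-place, no self loops,
        # immediates only from C0 — run it across built and simulated nets
        fixture_net.validate()
        pn.build_net(branch_cycle_table).validate()
        chain = pn.generate_truth_chain(15, seed=3)
        table = pn.simulate_trajectories(chain, 40, 11, seed=4)
        pn.build_net(table).validate()

    def test_reachability_graph_isomorphism(self, fixture_net, branch_cycle_table):
        for net in (fixture_net, pn.build_net(branch_cycle_table)):
            reach = pn.reachability_graph(net)
            place_graph = net.full_graph()
            reachable = {C0} | nx.descendants(place_graph, C0)
            sub = place_graph.subgraph(reachable)
            assert set(reach.nodes) == set(sub.nodes)
            assert set(reach.edges) == set(sub.edges)

    def test_edge_recovery_from_simulated_cells(self):
        chain = pn.generate_truth_chain(12, branching=1.8, cycle_fraction=0.3, seed=9)
        table = pn.simulate_trajectories(chain, 500, 11, seed=10)
        net = pn.build_net(table)
        observed = {
            (t.pre, t.post) for t in net.ordinary_transitions()
        }
        # exactness: nothing beyond the chain's edges is ever recovered
        assert observed <= set(chain.edges)
        # completeness for edges a trajectory traverses with prob > 0.01
        for edge, p_traverse in _edge_traversal_probs(chain, 11).items():
            if p_traverse > 0.01:
                assert edge in observed, (edge, p_traverse)


def _edge_traversal_probs(chain, n_timepoints):
    """Exact per-trajectory traversal probability of each edge.

    Dynamic programming over (state, traversed-yet) pairs.
    """
    states = sorted(chain.states)
    step = {
        s: [(s, chain.self_stay.get(s, 0.0))] + chain.successors(s) for s in states
    }
    out = {}
    for edge in chain.edges:
        dist = {(s, False): chain.initial_distribution.get(s, 0.0) for s in states}
        dist.update({(s, True): 0.0 for s in states})
        for _ in range(n_timepoints - 1):
            nxt = {k: 0.0 for k in dist}
            for (s, hit), mass in dist.items():
                if mass == 0.0:
                    continue
                for t, p in step[s]:
                    nxt[(t, hit or (s, t) == edge)] += mass * p
            dist = nxt
        out[edge] = sum(m for (s, hit), m in dist.items() if hit)
    return out
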