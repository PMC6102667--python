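"""CSTG construction, reachability control measures, CAG and driver heuristics."""

import itertools
import random
from fractions import Fraction

import networkx as nx
import pytest

from bncana import (
    BooleanNetwork,
    LookupTable,
    StructuralError,
    attractor_control,
    build_cag,
    build_cstg,
    build_stg,
    control_measures,
    control_report,
    find_attractors,
    mds_driver_set,
    random_nk,
    reachability_fractions,
    sc_driver_set,
)
from bncana.oracles import oracle_min_dominating_size, oracle_reachability


def constant_one_node():
    return BooleanNetwork([LookupTable("x", (), (1,))])


def identity_bits(n):
    return BooleanNetwork(
        [LookupTable(f"x{i+1}", (f"x{i+1}",), (0, 1)) for i in range(n)]
    )


def chain_net():
    return BooleanNetwork(
        [
            LookupTable("x1", ("x1",), (0, 1)),
            LookupTable("x2", ("x1",), (0, 1)),
            LookupTable("x3", ("x2",), (0, 1)),
        ]
    )


class TestCstg:
    def test_empty_driver_set_is_plain_stg(self):
        net = random_nk(4, 2, seed=0)
        g = build_cstg(net, ())
        assert all(d.get("kind") == "natural" for _, _, d in g.edges(data=True))
        assert all(d == 1 for _, d in g.out_degree)

    @pytest.mark.parametrize("n_drivers", [1, 2, 3])
    def test_controlled_out_edges_count(self, n_drivers):
        """Each configuration gains 2^|D| - 1 controlled transitions."""
        net = random_nk(3, 2, seed=5)
        g = build_cstg(net, net.names[:n_drivers])
        for v in g.nodes:
            controlled = [
                1
                for _, _, d in g.out_edges(v, data=True)
                if d.get("controlled") or d.get("kind") == "controlled"
            ]
            assert len(controlled) == 2 ** n_drivers - 1

    def test_unknown_driver_rejected(self):
        with pytest.raises(StructuralError):
            build_cstg(random_nk(3, 1, seed=1), ("nope",))


class TestReachability:
    def test_constant_node_hand_values(self):
        g = build_stg(constant_one_node())
        r = reachability_fractions(g)
        assert r[0] == 1 and r[1] == 0

    def test_strongly_connected_cstg_reaches_everything(self):
        net = random_nk(3, 2, seed=9)
        g = build_cstg(net, net.names)
        assert nx.is_strongly_connected(g)
        assert all(v == 1 for v in reachability_fractions(g).values())

    def test_terminal_fixed_point_reaches_nothing(self):
        net = identity_bits(2)
        r = reachability_fractions(build_stg(net))
        assert all(v == 0 for v in r.values())  # every state is a fixed point

    def test_matches_closure_oracle_on_random_graphs(self):
        rng = random.Random(12)
        for _ in range(30):
            g = nx.DiGraph()
            g.add_nodes_from(range(8))
            g.graph["n_automata"] = 3
            for u in range(8):
                for v in rng.sample(range(8), 2):
                    g.add_edge(u, v)
            fractions = reachability_fractions(g)
            reach = oracle_reachability(g.edges, g.nodes)
            for v in g.nodes:
                assert fractions[v] == Fraction(len(reach[v]), 7)

    def test_matches_oracle_on_random_cstgs(self):
        for seed in range(6):
            net = random_nk(5, 2, seed=seed)
            drivers = net.names[: seed % 3]
            g = build_cstg(net, drivers)
            fractions = reachability_fractions(g)
            reach = oracle_reachability(g.edges, g.nodes)
            for v in g.nodes:
                assert fractions[v] == Fraction(len(reach[v]), 2 ** 5 - 1)


class TestControlMeasures:
    def test_full_driver_set_fully_controls(self):
        for seed in (0, 1, 2):
            net = random_nk(3, 2, seed=seed)
            rep = control_measures(net, net.names)
            assert rep.mean_reachable == 1

    def test_empty_driver_set_controls_nothing(self):
        net = random_nk(4, 2, seed=7)
        rep = control_measures(net, ())
        assert rep.mean_controlled == 0

    def test_constant_one_node_hand_computation(self):
        """Natural STG 0->1,1->1 gives mean r = 1/2; driving x makes it 1."""
        net = constant_one_node()
        rep = control_measures(net, ("x",), per_configuration=True)
        assert rep.mean_reachable == 1
        assert rep.mean_reachable_empty == Fraction(1, 2)
        assert rep.mean_controlled == Fraction(1, 2)
        assert rep.per_configuration[1] == (Fraction(1), Fraction(0))

    def test_controlled_never_exceeds_reachable(self):
        for seed in range(5):
            net = random_nk(5, 2, seed=seed)
            for r in (0, 1, 2):
                rep = control_measures(net, net.names[:r])
                assert rep.mean_controlled <= rep.mean_reachable

    def test_monotone_under_driver_inclusion(self):
        """Adding drivers only adds CSTG edges, so R and A never decrease."""
        for seed in range(4):
            net = random_nk(5, 2, seed=seed)
            chains = [net.names[:i] for i in range(net.N + 1)]
            prev_r, prev_a = Fraction(-1), Fraction(-1)
            for d in chains:
                rep = control_measures(net, d)
                a = attractor_control(net, d)
                assert rep.mean_reachable >= prev_r
                assert a >= prev_a or prev_a == -1 or len(find_attractors(net)) == 1
                prev_r, prev_a = rep.mean_reachable, a


class TestCag:
    def test_vertices_equal_attractors(self):
        net = random_nk(5, 2, seed=6)
        n_att = len(find_attractors(net))
        for drivers in ((), net.names[:1], net.names):
            cag = build_cag(net, drivers)
            assert cag.number_of_nodes() == n_att

    def test_single_attractor_graph(self):
        net = random_nk(4, 2, bias=1.0, seed=0)
        cag = build_cag(net, ())
        assert cag.number_of_nodes() == 1 and cag.number_of_edges() == 0
        assert attractor_control(net, ()) == 1

    def test_fully_controlled_cag_complete(self):
        net = random_nk(4, 2, seed=14)
        cag = build_cag(net, net.names)
        n = cag.number_of_nodes()
        assert cag.number_of_edges() == n * (n - 1)
        assert attractor_control(net, net.names) == 1

    def test_two_identity_bits_single_driver(self):
        """Four fixed points; flipping x1 reaches exactly one other each."""
        net = identity_bits(2)
        assert len(find_attractors(net)) == 4
        assert attractor_control(net, ("x1",)) == Fraction(1, 3)

    def test_no_interventions_no_attractor_transitions(self):
        net = identity_bits(3)
        assert attractor_control(net, ()) == 0

    def test_fixture_cag_has_all_attractors(self):
        net = load_thaliana()
        cag = build_cag(net, ("UFO", "LUG", "CLF", "SEP", "TFL1"))
        assert cag.number_of_nodes() == 10


def load_thaliana():
    from bncana import load_example

    return load_example("thaliana")


class TestDriverHeuristics:
    def test_chain_driver_is_the_source(self):
        """x1 -> x2 -> x3 with x1 a pure source: the source must be driven."""
        net = BooleanNetwork(
            [
                LookupTable("x1", (), (1,)),
                LookupTable("x2", ("x1",), (0, 1)),
                LookupTable("x3", ("x2",), (0, 1)),
            ]
        )
        assert set(sc_driver_set(net).nodes) == {"x1"}

    def test_cycle_perfect_matching_gives_first_node(self):
        net = BooleanNetwork(
            [
                LookupTable("x1", ("x3",), (0, 1)),
                LookupTable("x2", ("x1",), (0, 1)),
                LookupTable("x3", ("x2",), (0, 1)),
            ]
        )
        assert set(sc_driver_set(net).nodes) == {"x1"}

    def test_edgeless_graph_needs_all_nodes(self):
        net = BooleanNetwork([LookupTable(f"x{i}", (), (1,)) for i in range(4)])
        assert set(sc_driver_set(net).nodes) == set(net.names)

    def test_sc_size_matches_matching_oracle(self):
        """|D| = max(N - maximum_matching, 1), with the matching found independently."""
        for seed in range(8):
            net = random_nk(6, 2, seed=seed)
            b = nx.DiGraph()
            left = {n: f"out_{n}" for n in net.names}
            right = {n: f"in_{n}" for n in net.names}
            for lut in net.nodes:
                for inp in lut.input_names:
                    b.add_edge(left[inp], right[lut.node_name])
            und = nx.Graph(b.edges)
            matching = nx.algorithms.bipartite.hopcroft_karp_matching(
                und, top_nodes=set(left.values()) & set(und.nodes)
            )
            m_size = sum(1 for k in matching if k.startswith("out_"))
            expected = max(net.N - m_size, 1)
            assert len(sc_driver_set(net)) == expected

    def test_out_star_dominated_by_center(self):
        net = BooleanNetwork(
            [LookupTable("hub", (), (1,))]
            + [LookupTable(f"leaf{i}", ("hub",), (0, 1)) for i in range(4)]
        )
        assert set(mds_driver_set(net).nodes) == {"hub"}

    def test_path_dominating_set_lexicographic(self):
        assert set(mds_driver_set(chain_net()).nodes) == {"x1", "x2"}

    def test_complete_digraph_single_node(self):
        names = ["a", "b", "c"]
        net = BooleanNetwork(
            [
                LookupTable(n, tuple(m for m in names if m != n), (0, 1, 1, 1))
                for n in names
            ]
        )
        assert set(mds_driver_set(net).nodes) == {"a"}

    def test_mds_size_matches_exhaustive_oracle(self):
        for seed in range(6):
            net = random_nk(6, 2, seed=seed)
            out = {
                n: {lut.node_name for lut in net.nodes if n in lut.input_names}
                for n in net.names
            }
            assert len(mds_driver_set(net)) == oracle_min_dominating_size(
                out, net.names
            )

    def test_report_carries_method_and_exactness(self):
        ds = mds_driver_set(random_nk(4, 2, seed=3))
        assert ds.method == "minimum_dominating_set" and ds.exact


class TestControlReport:
    def test_full_report_fields(self):
        net = identity_bits(2)
        rep = control_report(net, ("x1",))
        assert rep.mean_reachable_attractors == Fraction(1, 3)
        assert rep.mean_controlled == rep.mean_reachable - rep.mean_reachable_empty
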