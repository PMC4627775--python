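"""Metabolic network loading, lightest paths and union sub-networks."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nmrasca import connect_pair, load_network, union_subnetwork
from nmrasca.network import MetabolicNetwork


def _edgelist(tmp_path, rows, name="net.tsv"):
    path = tmp_path / name
    lines = ["source\ttarget\ttype"]
    lines += [f"{s}\t{t}\t{k}" for s, t, k in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


LINEAR = [
    ("m1", "R1", "substrate"), ("R1", "m2", "product"),
    ("m2", "R2", "substrate"), ("R2", "m3", "product"),
    ("m3", "R3", "substrate"), ("R3", "m4", "product"),
]


def _net(rows, side=()):  # build directly, bidirectional rows allowed
    g = nx.DiGraph()
    for s, t, k in rows:
        if k == "substrate":
            g.add_node(s, type="metabolite")
            g.add_node(t, type="reaction")
        else:
            g.add_node(s, type="reaction")
            g.add_node(t, type="metabolite")
        g.add_edge(s, t)
    return MetabolicNetwork(graph=g, side_compounds=frozenset(side))


def _reversible(rows):
    out = list(rows)
    out += [(t, s, "product" if k == "substrate" else "substrate") for s, t, k in rows]
    return out


def path_weight_oracle(net, nodes, weighting):
    from nmrasca.network import _node_cost

    return sum(_node_cost(net, v, weighting) for v in nodes[1:])


def brute_force_min(net, a, b, weighting):
    """Exhaustive enumeration over all simple paths."""
    best = None
    blocked = net.side_compounds - {a, b}
    g = net.graph.subgraph(set(net.graph.nodes) - blocked)
    for nodes in nx.all_simple_paths(g, a, b):
        w = path_weight_oracle(net, nodes, weighting)
        key = (w, tuple(nodes))
        if best is None or key < best:
            best = key
    return best


class TestLoad:
    def test_linear_toy(self, tmp_path):
        net = load_network(_edgelist(tmp_path, LINEAR))
        assert len(net.metabolites) == 4
        assert len(net.reactions) == 3

    def test_reversible_column_adds_both_arcs(self, tmp_path):
        path = tmp_path / "rev.tsv"
        path.write_text(
            "source\ttarget\ttype\treversible\n"
            "m1\tR1\tsubstrate\tTrue\n"
            "R1\tm2\tproduct\tTrue\n"
        )
        net = load_network(path)
        assert net.graph.has_edge("m1", "R1") and net.graph.has_edge("R1", "m1")
        assert net.graph.has_edge("R1", "m2") and net.graph.has_edge("m2", "R1")

    def test_edgelist_round_trip(self, tmp_path):
        net = load_network(_edgelist(tmp_path, LINEAR))
        out = tmp_path / "out.tsv"
        net.to_edgelist(out)
        back = load_network(out)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(back.graph.edges) == set(net.graph.edges)

    def test_non_bipartite_rejected(self):
        g = nx.DiGraph()
        g.add_node("a", type="metabolite")
        g.add_node("b", type="metabolite")
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="bipartite"):
            MetabolicNetwork(graph=g)


class TestConnectPair:
    def test_adjacent_single_reaction(self):
        net = _net(LINEAR)
        pp = connect_pair(net, "m1", "m2")
        assert pp.reachable
        assert pp.reactions == ("R1",)
        assert pp.metabolites == ("m1", "m2")

    def test_hub_cofactor_avoided_under_degree_weighting(self):
        # diamond: short branch via hub h (high degree), long branch via x, y
        rows = [
            ("a", "R1", "substrate"), ("R1", "h", "product"),
            ("h", "R2", "substrate"), ("R2", "b", "product"),
            ("a", "R3", "substrate"), ("R3", "x", "product"),
            ("x", "R4", "substrate"), ("R4", "y", "product"),
            ("y", "R5", "substrate"), ("R5", "b", "product"),
        ]
        # inflate the hub's degree with side reactions
        for i in range(6):
            rows += [("h", f"Rh{i}", "substrate"), (f"Rh{i}", f"z{i}", "product")]
        net = _net(_reversible(rows))
        deg = connect_pair(net, "a", "b", weighting="degree")
        assert "h" not in deg.nodes
        w, nodes = brute_force_min(net, "a", "b", "degree")
        assert deg.weight == pytest.approx(w)
        assert deg.nodes == nodes
        # unweighted traversal takes the short branch through the hub
        short = connect_pair(net, "a", "b", weighting="unweighted")
        assert "h" in short.nodes

    def test_symmetry_on_reversible_network(self):
        net = _net(_reversible(LINEAR))
        fwd = connect_pair(net, "m1", "m4")
        rev = connect_pair(net, "m4", "m1")
        assert fwd.nodes == tuple(reversed(rev.nodes))

    def test_unknown_and_unreachable(self):
        net = _net(LINEAR)
        with pytest.raises(KeyError):
            connect_pair(net, "m1", "nope")
        # directed chain: m4 cannot reach m1
        back = connect_pair(net, "m4", "m1")
        assert not back.reachable and back.nodes == ()

    def test_side_compound_not_traversed(self):
        rows = _reversible([
            ("a", "R1", "substrate"), ("R1", "w", "product"),
            ("w", "R2", "substrate"), ("R2", "b", "product"),
            ("a", "R3", "substrate"), ("R3", "c", "product"),
            ("c", "R4", "substrate"), ("R4", "b", "product"),
        ])
        net = _net(rows, side={"w"})
        pp = connect_pair(net, "a", "b")
        assert "w" not in pp.nodes and "c" in pp.nodes
        # but a side compound may be an endpoint
        assert connect_pair(net, "a", "w").reachable

    @pytest.mark.parametrize("weighting", ["degree", "unweighted"])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_toys(self, seed, weighting):
        rng = np.random.default_rng(seed)
        n_m, n_r = 6, 6  # 12 nodes
        g = nx.DiGraph()
        mets = [f"m{i}" for i in range(n_m)]
        rxns = [f"r{i}" for i in range(n_r)]
        for m in mets:
            g.add_node(m, type="metabolite")
        for r in rxns:
            g.add_node(r, type="reaction")
        for r in rxns:
            subs = rng.choice(mets, size=rng.integers(1, 3), replace=False)
            prods = rng.choice(mets, size=rng.integers(1, 3), replace=False)
            for m in subs:
                g.add_edge(m, r)
            for m in prods:
                g.add_edge(r, m)
        net = MetabolicNetwork(graph=g)
        for a, b in itertools.combinations(mets, 2):
            got = connect_pair(net, a, b, weighting=weighting)
            oracle = brute_force_min(net, a, b, weighting)
            if oracle is None:
                assert not got.reachable
            else:
                assert got.reachable
                assert got.weight == pytest.approx(oracle[0])
                assert got.nodes == oracle[1]  # lexicographic tie-break too


class TestUnion:
    def test_collinear_biomarkers_give_the_path(self):
        net = _net(LINEAR)
        sub = union_subnetwork(net, ["m1", "m2", "m4"])
        assert set(sub.graph.nodes) == {"m1", "R1", "m2", "R2", "m3", "R3", "m4"}
        # no orphans: every node on at least one accepted path
        assert all(sub.provenance[n] for n in sub.graph.nodes)

    def test_intermediate_provenance(self):
        # glucose-like and glycerol-like connect through an inositol-like hub
        rows = _reversible([
            ("glucose", "Rg", "substrate"), ("Rg", "inositol", "product"),
            ("inositol", "Ri", "substrate"), ("Ri", "glycerol", "product"),
        ])
        net = _net(rows)
        sub = union_subnetwork(net, ["glucose", "glycerol"])
        assert "inositol" in sub.graph.nodes
        assert sub.provenance["inositol"] == {("glucose", "glycerol")}

    def test_disconnected_components_reported(self):
        rows = LINEAR + [
            ("p1", "Q1", "substrate"), ("Q1", "p2", "product"),
        ]
        net = _net(_reversible(rows))
        sub = union_subnetwork(net, ["m1", "m4", "p1", "p2"])
        assert ("m1", "p1") in sub.unreachable_pairs
        comps = list(nx.weakly_connected_components(sub.graph))
        assert len(comps) == 2

    def test_order_invariance(self):
        net = _net(_reversible(LINEAR))
        a = union_subnetwork(net, ["m1", "m3", "m4"])
        b = union_subnetwork(net, ["m4", "m1", "m3"])
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.provenance == b.provenance

    def test_all_unreachable_is_empty_with_report(self):
        rows = [
            ("a", "R1", "substrate"), ("R1", "b", "product"),
            ("c", "R2", "substrate"), ("R2", "d", "product"),
        ]
        net = _net(rows)
        sub = union_subnetwork(net, ["a", "c"])
        assert sub.graph.number_of_nodes() == 0
        assert sub.unreachable_pairs == [("a", "c")]

    def test_graphml_export(self, tmp_path):
        net = _net(_reversible(LINEAR))
        sub = union_subnetwork(net, ["m1", "m4"])
        out = tmp_path / "sub.graphml"
        sub.export(out)
        back = nx.read_graphml(out)
        assert set(back.nodes) == set(sub.graph.nodes)
        assert back.nodes["m2"]["provenance"] == "m1|m4"
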