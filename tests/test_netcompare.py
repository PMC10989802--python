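"""Cross-network comparisons: presence matrices, Venn regions, intersections,
edge distances and taxon-source ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netkomp import (CooccurrenceNetwork, NetworkCollection, ValidationError,
                     edge_comp, edge_node_distance, edge_distance_test,
                     edge_tax_comp, node_comp, subset_network, venn_counts,
                     venn_counts_table)


def _net(edges, phylum=None, signs=None):
    net = CooccurrenceNetwork()
    for i, (u, v) in enumerate(edges):
        w = -0.7 if signs and signs[i] == "-" else 0.8
        for n in (u, v):
            if phylum and n in phylum:
                net.add_node(n, Phylum=phylum[n])
        net.add_edge(u, v, weight=w)
    return net


@pytest.fixture()
def three_nets():
    coll = NetworkCollection()
    coll["X"] = _net([("a", "b"), ("b", "c"), ("c", "d")])
    coll["Y"] = _net([("a", "b"), ("c", "d"), ("d", "e")])
    coll["Z"] = _net([("a", "b"), ("b", "c"), ("d", "e"), ("e", "f")])
    return coll


class TestPresence:
    def test_identical_networks_give_all_ones(self):
        coll = NetworkCollection()
        coll["p"] = _net([("a", "b"), ("b", "c")])
        coll["q"] = _net([("a", "b"), ("b", "c")])
        assert (node_comp(coll).matrix.values == 1).all()
        assert (edge_comp(coll).matrix.values == 1).all()

    def test_disjoint_node_sets_give_block_pattern(self):
        coll = NetworkCollection()
        coll["p"] = _net([("a", "b")])
        coll["q"] = _net([("c", "d")])
        pm = node_comp(coll)
        assert (pm.matrix.sum(axis=1) == 1).all()  # each node in exactly one

    def test_cells_match_membership_oracle(self, three_nets):
        pm = node_comp(three_nets)
        for item in pm.items:
            for label in pm.networks:
                assert pm.matrix.at[item, label] == \
                    int(item in three_nets[label].graph.nodes)
        em = edge_comp(three_nets)
        for item in em.items:
            a, b = item.split(" -- ")
            for label in em.networks:
                assert em.matrix.at[item, label] == \
                    int(three_nets[label].has_edge(a, b))

    def test_sign_matching_flag(self):
        coll = NetworkCollection()
        coll["pos"] = _net([("a", "b")], signs=["+"])
        coll["neg"] = _net([("a", "b")], signs=["-"])
        lax = edge_comp(coll)
        assert (lax.matrix.values == 1).all()
        strict = edge_comp(coll, match_sign=True)
        assert (strict.matrix.sum(axis=1) == 1).all()

    def test_requires_two_networks(self):
        coll = NetworkCollection()
        coll["only"] = _net([("a", "b")])
        with pytest.raises(ValidationError):
            node_comp(coll)


class TestVenn:
    def test_identical_networks_fill_only_the_full_region(self):
        coll = NetworkCollection()
        for lbl in "pq":
            coll[lbl] = _net([("a", "b"), ("b", "c")])
        counts = venn_counts(edge_comp(coll))
        assert counts == {frozenset({"p", "q"}): 2}

    def test_disjoint_networks_fill_only_singletons(self):
        coll = NetworkCollection()
        coll["p"] = _net([("a", "b")])
        coll["q"] = _net([("c", "d")])
        counts = venn_counts(edge_comp(coll))
        assert counts == {frozenset({"p"}): 1, frozenset({"q"}): 1}

    @pytest.mark.parametrize("n_extra", [0, 1])  # 3- and 4-network fixtures
    def test_counts_match_inclusion_exclusion_oracle(self, three_nets, n_extra):
        if n_extra:
            three_nets["W"] = _net([("a", "b"), ("e", "f")])
        pm = edge_comp(three_nets)
        counts = venn_counts(pm)
        # oracle: frozenset signature per item, tallied independently
        sets = {lbl: three_nets[lbl].edge_keys() for lbl in three_nets}
        union = set().union(*sets.values())
        expected = {}
        for a, b in union:
            sig = frozenset(l for l in sets if (a, b) in sets[l])
            expected[sig] = expected.get(sig, 0) + 1
        assert counts == expected
        assert sum(counts.values()) == len(pm.items) == len(union)

    def test_region_counts_are_permutation_invariant(self, three_nets):
        counts = venn_counts(edge_comp(three_nets))
        renamed = NetworkCollection()
        mapping = {"X": "Z2", "Y": "X2", "Z": "Y2"}
        for old, new in mapping.items():
            renamed[new] = three_nets[old]
        counts2 = venn_counts(edge_comp(renamed))
        remap = {frozenset(mapping[l] for l in sig): c for sig, c in counts.items()}
        assert counts2 == remap

    def test_table_rows_cover_all_regions(self, three_nets):
        tab = venn_counts_table(edge_comp(three_nets))
        assert len(tab) == 2 ** 3 - 1
        assert tab["count"].sum() == len(edge_comp(three_nets).items)


class TestSubsetNetwork:
    def test_intersection_of_identical_networks_is_idempotent(self):
        coll = NetworkCollection()
        for lbl in "pq":
            coll[lbl] = _net([("a", "b"), ("b", "c")])
        inter = subset_network(coll, "intersection")
        assert inter.edge_keys() == coll["p"].edge_keys()

    def test_disjoint_edge_sets_give_empty_network(self):
        coll = NetworkCollection()
        coll["p"] = _net([("a", "b")])
        coll["q"] = _net([("c", "d")])
        inter = subset_network(coll, "intersection")
        assert inter.node_count == 0 and inter.edge_count == 0

    def test_intersection_matches_set_algebra_oracle(self, three_nets):
        inter = subset_network(three_nets, "intersection")
        expected = set.intersection(*(three_nets[l].edge_keys()
                                      for l in three_nets))
        assert inter.edge_keys() == expected
        assert set(inter.graph.nodes) == {n for e in expected for n in e}

    def test_exact_region_signature(self, three_nets):
        only_xz = subset_network(three_nets, frozenset({"X", "Z"}))
        sets = {l: three_nets[l].edge_keys() for l in three_nets}
        expected = {e for e in sets["X"] & sets["Z"] if e not in sets["Y"]}
        assert only_xz.edge_keys() == expected

    def test_attributes_copied_from_first_containing_network(self, three_nets):
        three_nets["X"].edge_data("a", "b")["p_adj"] = 0.011
        inter = subset_network(three_nets, "intersection")
        assert inter.edge_data("a", "b")["p_adj"] == 0.011


class TestEdgeNodeDistance:
    def _dist(self, names, fill=0.0):
        n = len(names)
        m = np.full((n, n), fill)
        np.fill_diagonal(m, 0.0)
        return pd.DataFrame(m, index=names, columns=names)

    def test_all_zero_matrix_gives_zero_distances(self, three_nets):
        names = list("abcdef")
        tab = edge_node_distance(three_nets, self._dist(names))
        assert (tab["distance"] == 0).all()
        assert len(tab) == sum(net.edge_count for net in three_nets.values())

    def test_symmetric_lookup_and_tree_fixture_values(self, tmp_path):
        from netkomp import read_tree_distances
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);")
        d = read_tree_distances(p)
        coll = NetworkCollection()
        coll["m"] = _net([("B", "A"), ("A", "C")])
        coll["n"] = _net([("B", "C")])
        tab = edge_node_distance(coll, d)
        got = {(r.node1, r.node2): r.distance for r in tab.itertuples()}
        assert got == {("A", "B"): 2.0, ("A", "C"): 4.0, ("B", "C"): 4.0}

    def test_edges_with_missing_endpoints_are_dropped(self, three_nets):
        names = list("abcd")  # e, f missing
        tab = edge_node_distance(three_nets, self._dist(names, fill=1.0))
        assert {tuple(r) for r in tab[["node1", "node2"]].values} <= \
            set(itertools.combinations(names, 2))

    def test_asymmetric_matrix_rejected(self, three_nets):
        d = self._dist(list("abcdef"))
        d.iloc[0, 1] = 5.0
        with pytest.raises(ValidationError, match="symmetric"):
            edge_node_distance(three_nets, d)

    def test_distance_test_runs_over_network_groups(self):
        rng = np.random.default_rng(0)
        coll = NetworkCollection()
        names = [f"n{i}" for i in range(40)]
        m = np.abs(rng.normal(0, 1, (40, 40)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = pd.DataFrame(m, index=names, columns=names)
        coll["u"] = _net([(names[i], names[i + 1]) for i in range(0, 20, 2)])
        coll["v"] = _net([(names[i], names[i + 1]) for i in range(20, 38, 2)])
        tab = edge_node_distance(coll, d)
        res = edge_distance_test(tab)
        assert set(res.letters) == {"u", "v"}


class TestEdgeTaxComp:
    def test_single_phylum_gives_ratio_one(self):
        coll = NetworkCollection()
        coll["n1"] = _net([("a", "b"), ("b", "c")],
                          phylum={"a": "P", "b": "P", "c": "P"})
        coll["n2"] = _net([("a", "c")], phylum={"a": "P", "c": "P"})
        tab = edge_tax_comp(coll)
        assert list(tab.index) == ["P -- P"]
        assert tab.loc["P -- P"].tolist() == [1.0, 1.0]

    def test_ratios_sum_to_one_when_all_classified(self):
        phylum = {"a": "P1", "b": "P1", "c": "P2", "d": "P3"}
        coll = NetworkCollection()
        coll["x"] = _net([("a", "b"), ("a", "c"), ("c", "d")], phylum=phylum)
        coll["y"] = _net([("b", "c"), ("b", "d")], phylum=phylum)
        tab = edge_tax_comp(coll)
        assert tab.sum(axis=0).values == pytest.approx([1.0, 1.0])
        assert ((tab.values >= 0) & (tab.values <= 1)).all()

    def test_counts_match_brute_force_pair_tally(self):
        phylum = {"a": "P1", "b": "P1", "c": "P2", "d": "P3", "e": "P2"}
        edges = [("a", "b"), ("a", "c"), ("c", "e"), ("d", "e"), ("b", "d")]
        signs = ["+", "+", "-", "+", "+"]
        coll = NetworkCollection()
        coll["w"] = _net(edges, phylum=phylum, signs=signs)
        coll["w2"] = _net(edges[:2], phylum=phylum)
        tab = edge_tax_comp(coll, sign="positive")
        pos_edges = [e for e, s in zip(edges, signs) if s == "+"]
        tally = {}
        for u, v in pos_edges:
            pair = tuple(sorted([phylum[u], phylum[v]]))
            tally[pair] = tally.get(pair, 0) + 1
        for (p1, p2), c in tally.items():
            assert tab.at[f"{p1} -- {p2}", "w"] == pytest.approx(c / len(pos_edges))

    def test_missing_taxonomy_grouped_as_unclassified(self):
        coll = NetworkCollection()
        coll["n"] = _net([("a", "b")], phylum={"a": "P1"})
        tab = edge_tax_comp(coll)
        assert "P1 -- unclassified" in tab.index

    def test_no_edges_of_requested_sign_gives_nan(self):
        coll = NetworkCollection()
        coll["n"] = _net([("a", "b")], phylum={"a": "P", "b": "P"})
        tab = edge_tax_comp(coll, sign="negative")
        assert tab.empty or tab["n"].isna().all()


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                min_size=1, max_size=30))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_venn_counts_always_sum_to_item_total(memberships):
    """Region counts partition the items for any presence pattern."""
    from netkomp import PresenceMatrix
    rows = [m for m in memberships if any(m)]
    if not rows:
        return
    mat = pd.DataFrame(rows, columns=["A", "B", "C"],
                       index=[f"i{k}" for k in range(len(rows))]).astype(int)
    counts = venn_counts(PresenceMatrix(mat))
    assert sum(counts.values()) == len(rows)
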