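"""Tree structure, Newick I/O, split algebra and the topology builders."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_tree
from lbasim.topologies import (
    build_topology_a,
    build_topology_b,
    topology_a_spec,
    topology_b_spec,
)
from lbasim.trees import (
    Bipartition,
    NewickError,
    bipartitions,
    nni_neighbors,
    parse_newick,
    prune_taxa,
    rf_distance,
    write_newick,
)


def sides(tree):
    return {b.side for b in bipartitions(tree)}


class TestNewick:
    def test_parse_simple(self):
        t = parse_newick("(a:1,b:2,(c:3,d:4):5);")
        assert t.leaf_labels() == {"a", "b", "c", "d"}
        assert len(bipartitions(t)) == 1
        assert Bipartition.from_split({"c", "d"}, t.leaf_labels()) in bipartitions(t)

    def test_round_trip_preserves_splits_and_lengths(self, rng):
        t = random_tree([f"x{i}" for i in range(9)], rng)
        again = parse_newick(write_newick(t))
        assert rf_distance(t, again) == 0
        for a, b in [("x0", "x5"), ("x2", "x8")]:
            assert t.path_length(a, b) == pytest.approx(
                again.path_length(a, b), rel=1e-9
            )

    @pytest.mark.parametrize(
        "bad",
        ["((a:1,b:2);", "(a:1,b:2)", "(a:1,a:2,c:1);", "(a:1,(b:2,c:1));x"],
    )
    def test_malformed_input_raises_with_position(self, bad):
        with pytest.raises(NewickError) as err:
            parse_newick(bad)
        assert err.value.pos >= 0

    def test_agrees_with_dendropy_parser(self, rng):
        nwk = write_newick(random_tree([f"t{i}" for i in range(8)], rng))
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        assert {lf.taxon.label for lf in dt.leaf_node_iter()} == set(
            parse_newick(nwk).leaf_labels()
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 12))
    def test_round_trip_property(self, seed, n):
        t = random_tree([f"L{i}" for i in range(n)], np.random.default_rng(seed))
        assert rf_distance(t, parse_newick(write_newick(t))) == 0


class TestSplits:
    def test_counts(self, rng):
        assert len(bipartitions(random_tree(list("abcdefghijk"), rng))) == 8
        assert len(bipartitions(parse_newick("((a:1,b:1):1,(c:1,d:1):1);"))) == 1
        assert len(bipartitions(parse_newick("(a:1,b:1,c:1,d:1);"))) == 0

    def test_rf_identity_and_nni_distance(self, rng):
        t = random_tree(list("abcdefg"), rng)
        assert rf_distance(t, t) == 0
        for nb, _edge in nni_neighbors(t):
            assert rf_distance(t, nb) == 2

    def test_rf_leafset_mismatch(self, rng):
        t1 = random_tree(list("abcd"), rng)
        t2 = random_tree(list("abce"), rng)
        with pytest.raises(ValueError, match="leaf sets differ"):
            rf_distance(t1, t2)

    def test_rf_matches_dendropy(self, rng):
        taxa = dendropy.TaxonNamespace()
        for _ in range(10):
            a = random_tree(list("abcdefgh"), rng)
            b = random_tree(list("abcdefgh"), rng)
            da = dendropy.Tree.get(data=write_newick(a), schema="newick",
                                   taxon_namespace=taxa)
            db = dendropy.Tree.get(data=write_newick(b), schema="newick",
                                   taxon_namespace=taxa)
            da.encode_bipartitions(), db.encode_bipartitions()
            expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert rf_distance(a, b) == expected

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_rf_is_a_metric_on_8_leaf_trees(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (random_tree(list("abcdefgh"), rng) for _ in range(3))
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


class TestPrune:
    def test_restriction_matches_split_restriction(self, rng):
        t = random_tree(list("abcdefg"), rng)
        keep = {"a", "c", "d", "f", "g"}
        restricted = prune_taxa(t, keep)
        want = set()
        for side in sides(t):
            s = side & keep
            if 1 < len(s) < len(keep) - 1:
                want.add(Bipartition.from_split(s, keep).side)
        assert sides(restricted) == want

    def test_three_leaf_star_and_path_lengths(self, rng):
        t = random_tree(list("abcde"), rng)
        small = prune_taxa(t, {"a", "b", "c"})
        assert len(small.internal_edges()) == 0
        assert small.path_length("a", "b") == pytest.approx(
            t.path_length("a", "b"), rel=1e-9
        )

    def test_unknown_label(self, rng):
        with pytest.raises(ValueError, match="not in tree"):
            prune_taxa(random_tree(list("abcd"), rng), {"a", "b", "z"})


class TestBuilders:
    def test_topology_a_designated_edges(self):
        t = build_topology_a(ltb=0.1, sib=0.01, rb=0.05)
        assert t.n_leaves == 11
        assert len(t.internal_edges()) == 8
        ids = t.leaf_ids()
        (n3, l3), = t.neighbors(ids["t3"]).items()
        assert l3 == pytest.approx(0.1)
        # the {t3,t4} cherry stem carries SiB
        stem, = [
            (u, v) for u, v in t.internal_edges()
            if t.side_leaves(u, v) in ({"t3", "t4"}, t.leaf_labels() - {"t3", "t4"})
        ]
        assert t.length(*stem) == pytest.approx(0.01)
        assert frozenset({"t3", "t4"}) in sides(t)
        assert frozenset({"t3", "t7"}) not in sides(t)
        assert frozenset(t.leaf_labels() - {"t3", "t7"}) not in sides(t)

    def test_topology_a_uniform_lengths(self):
        t = build_topology_a(ltb=0.05, sib=0.05, rb=0.05)
        assert t.n_leaves == 11
        assert len(t.internal_edges()) == 8
        assert all(ln == pytest.approx(0.05) for _, _, ln in t.edges())

    def test_topology_b_designated_edges(self):
        t = build_topology_b(lib=1.5, sib=0.01, rb=0.05)
        assert t.n_leaves == 11
        assert len(t.internal_edges()) == 8
        clade_a = frozenset({"t1", "t2", "t3", "t4"})
        clade_b = frozenset({"t7", "t8", "t9", "t10", "t11"})
        lengths = {}
        for u, v in t.internal_edges():
            side = t.side_leaves(u, v)
            side = min(side, t.leaf_labels() - side, key=sorted)
            lengths[side] = t.length(u, v)
        assert lengths[clade_a] == pytest.approx(1.5)
        assert lengths[min(clade_b, t.leaf_labels() - clade_b, key=sorted)] \
            == pytest.approx(1.5)
        # central edge separates {t1..t4, t5} from the rest
        central = frozenset({"t1", "t2", "t3", "t4", "t5"})
        assert lengths[min(central, t.leaf_labels() - central, key=sorted)] \
            == pytest.approx(0.01)
        # t5 and t6 are not sisters
        assert frozenset({"t5", "t6"}) not in sides(t)

    @pytest.mark.parametrize("builder,param", [
        (lambda: build_topology_a(-0.1, 0.01), "ltb"),
        (lambda: build_topology_a(0.1, -0.01), "sib"),
        (lambda: build_topology_b(0.1, 0.01, rb=-1), "rb"),
    ])
    def test_negative_lengths_name_the_parameter(self, builder, param):
        with pytest.raises(ValueError, match=param):
            builder()

    def test_specs_reference_existing_elements(self):
        ta, tb = build_topology_a(0.3, 0.1), build_topology_b(0.3, 0.1)
        sa, sb = topology_a_spec(), topology_b_spec()
        assert set(sa.focal_long) <= ta.leaf_labels()
        assert sa.focal_short_pair is None
        assert set(sb.focal_short_pair) <= tb.leaf_labels()
        for clade in sb.focal_long:
            assert clade < tb.leaf_labels()

    def test_nni_neighbor_count(self):
        t = build_topology_a(0.3, 0.1)
        assert len(nni_neighbors(t)) == 16  # two per internal edge
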