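"""Tree parsing, writing, rooting, MRCA and patristic distances."""

import numpy as np
import pytest

from phyloconstraint.errors import (
    DuplicateTipLabelError,
    NewickParseError,
    NonMonophyleticOutgroupError,
    UnknownLabelError,
    UnrootedTreeError,
    ValidationError,
)
from phyloconstraint.treeio import parse_newick, write_newick

from conftest import mrca_oracle, path_sum_oracle, random_tree


class TestParseNewick:
    def test_two_tip_tree_distance(self):
        t = parse_newick("(A:1,B:2);")
        assert t.patristic("A", "B") == pytest.approx(3.0)

    def test_three_tip_internal_depth(self, three_tip_tree):
        m = three_tip_tree.mrca({"A", "B"})
        assert three_tip_tree.depths()[m.node_id] == pytest.approx(2.0)

    def test_quoted_labels_and_comments(self):
        t = parse_newick("('sp. PCC 7120':1,[note]B:2);")
        assert "sp. PCC 7120" in t.tip_labels()

    def test_internal_label_retained(self):
        t = parse_newick("((A:1,B:1)node1:2,C:3);")
        internal = [n for n in t.nodes.values() if not n.is_tip and n.parent is not None]
        assert internal[0].label == "node1"

    def test_missing_semicolon_is_parse_error(self):
        with pytest.raises(NewickParseError):
            parse_newick("(A:1,B:2)")

    def test_unbalanced_parens_is_parse_error(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:2);")

    def test_duplicate_tip_label_rejected(self):
        with pytest.raises((DuplicateTipLabelError, NewickParseError)):
            parse_newick("(A:1,A:2);")

    def test_missing_branch_length_warns_and_defaults_zero(self):
        with pytest.warns(UserWarning):
            t = parse_newick("(A,B:1);")
        assert t.patristic("A", "B") == pytest.approx(1.0)


class TestWriteNewick:
    def test_round_trip_preserves_distances(self, rng):
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(4, 21)))
            t2 = parse_newick(write_newick(t))
            labels = t.tip_labels()
            assert sorted(labels) == sorted(t2.tip_labels())
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert t2.patristic(a, b) == pytest.approx(
                        t.patristic(a, b), rel=1e-9
                    )

    def test_metacharacter_labels_are_quoted(self):
        t = parse_newick("('sp. PCC 7120':1,B:2);")
        out = write_newick(t)
        assert "'sp. PCC 7120'" in out
        assert "sp. PCC 7120" in parse_newick(out).tip_labels()


class TestMrca:
    def test_pair_and_root(self, three_tip_tree):
        t = three_tip_tree
        assert t.tipset(t.mrca({"A", "B"}).node_id) == {"A", "B"}
        assert t.mrca({"A", "C"}).node_id == t.root_id

    def test_matches_ancestor_path_oracle(self, rng):
        for _ in range(30):
            t = random_tree(rng, int(rng.integers(4, 16)))
            labels = t.tip_labels()
            k = int(rng.integers(2, len(labels) + 1))
            subset = set(rng.choice(labels, size=k, replace=False).tolist())
            assert t.mrca(subset).node_id == mrca_oracle(t, subset)

    def test_unknown_label_and_unrooted_state(self, three_tip_tree):
        with pytest.raises(UnknownLabelError):
            three_tip_tree.mrca({"A", "missing"})
        unrooted = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(UnrootedTreeError, match="root_by_outgroup"):
            unrooted.mrca({"A", "B"})


class TestPatristic:
    def test_hand_path_sums(self, three_tip_tree):
        t = three_tip_tree
        assert t.patristic("A", "C") == pytest.approx(6.0)
        assert t.patristic("A", "B") == pytest.approx(2.0)
        assert t.patristic("A", "A") == 0.0

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(4, 15)))
            labels = t.tip_labels()
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert t.patristic(a, b) == pytest.approx(
                        path_sum_oracle(t, a, b), rel=1e-12
                    )

    def test_four_point_condition_on_quartets(self, rng):
        t = random_tree(rng, 12)
        labels = t.tip_labels()
        for _ in range(200):
            a, b, c, d = rng.choice(labels, size=4, replace=False)
            s1 = t.patristic(a, b) + t.patristic(c, d)
            s2 = t.patristic(a, c) + t.patristic(b, d)
            s3 = t.patristic(a, d) + t.patristic(b, c)
            top = sorted([s1, s2, s3])
            assert top[1] == pytest.approx(top[2], rel=1e-9)


class TestDistancesFrom:
    def test_from_root_and_internal(self, three_tip_tree):
        t = three_tip_tree
        assert t.distances_from(t.root_id) == pytest.approx({"A": 3, "B": 3, "C": 3})
        m = t.mrca({"A", "B"})
        assert t.distances_from(m) == pytest.approx({"A": 1, "B": 1, "C": 5})

    def test_clade_offset_invariant(self, rng):
        # distances from root restricted to a clade = distances from the
        # clade MRCA + d(root, MRCA)
        for _ in range(10):
            t = random_tree(rng, 10)
            from_root = t.distances_from(t.root_id)
            for nid, node in t.nodes.items():
                if node.is_tip or nid == t.root_id:
                    continue
                offset = t.node_distance(t.root_id, nid)
                from_node = t.distances_from(nid)
                for tip in t.tipset(nid):
                    assert from_root[tip] == pytest.approx(from_node[tip] + offset)


class TestRootByOutgroup:
    def test_outgroup_excluded_from_ingroup_mrca(self):
        t = parse_newick("(((A:1,B:1):1,C:2):1,O:4);")
        rooted = t.root_by_outgroup({"O"})
        ingroup_mrca = rooted.mrca({"A", "B", "C"})
        assert "O" not in rooted.tipset(ingroup_mrca.node_id)

    def test_patristic_invariant_under_rooting(self, rng):
        for _ in range(25):
            t = random_tree(rng, int(rng.integers(4, 12)))
            labels = t.tip_labels()
            og = labels[0]
            rooted = t.root_by_outgroup({og})
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert rooted.patristic(a, b) == pytest.approx(
                        t.patristic(a, b), rel=1e-12
                    )

    def test_root_bisects_stem(self):
        # in the unrooted tree the stem separating O from (A,B) has length
        # 2 + 4 = 6 (the stored degree-2 root sits on it); each side gets 3
        t = parse_newick("((A:1,B:1):2,O:4);")
        rooted = t.root_by_outgroup({"O"})
        og_id = rooted.tip_id("O")
        assert rooted.nodes[og_id].parent == rooted.root_id
        assert rooted.nodes[og_id].length == pytest.approx(3.0)
        assert rooted.patristic("A", "O") == pytest.approx(7.0)

    def test_root_bisects_stem_polytomy_root(self):
        # with a basal polytomy the outgroup's own edge is the stem
        t = parse_newick("((A:1,B:1):2,C:3,O:4);")
        rooted = t.root_by_outgroup({"O"})
        og_id = rooted.tip_id("O")
        assert rooted.nodes[og_id].length == pytest.approx(2.0)
        assert rooted.patristic("A", "O") == pytest.approx(7.0)

    def test_all_tips_outgroup_is_error(self, three_tip_tree):
        with pytest.raises(ValidationError):
            three_tip_tree.root_by_outgroup({"A", "B", "C"})

    def test_non_monophyletic_outgroup_rejected(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(NonMonophyleticOutgroupError):
            t.root_by_outgroup({"A", "C"})


def test_validation_report_mentions_zero_length_branches():
    t = parse_newick("((A:0,B:1):1,C:2);")
    report = t.validation_report()
    assert "zero_length_branches\t1" in report
    assert "n_tips\t3" in report


def test_dendropy_cross_check(rng):
    """Patristic distances agree with dendropy's phylogenetic distance matrix."""
    import dendropy

    t = random_tree(rng, 10)
    dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in dt.taxon_namespace}
    labels = t.tip_labels()
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert t.patristic(a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9
            )
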