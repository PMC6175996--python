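"""Alignment I/O, distance corrections, and neighbor joining."""

import math

import numpy as np
import pytest

from phyloconstraint.aligndist import (
    Alignment,
    DistanceEstimate,
    DistanceMatrix,
    correct_distance,
    distance_matrix,
    neighbor_joining,
    p_distance,
    read_fasta_alignment,
    write_fasta_alignment,
)
from phyloconstraint.errors import (
    AlignmentError,
    InsufficientOverlapError,
    ValidationError,
)
from phyloconstraint.synthetic_data import generate_yule_tree, simulate_alignment

from conftest import random_tree


class TestAlignmentIO:
    def test_read_preserves_order_and_case_normalizes(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">b\nacdef\n>a\nACDEF\n")
        aln = read_fasta_alignment(path, "protein")
        assert aln.labels() == ["b", "a"]
        assert aln.sequence("b") == "ACDEF"
        assert aln.length == 5

    def test_ragged_alignment_names_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACDEF\n>b\nACD\n")
        with pytest.raises(AlignmentError, match="b"):
            read_fasta_alignment(path, "protein")

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(AlignmentError):
            read_fasta_alignment(path, "protein")

    def test_invalid_protein_residue_named(self):
        with pytest.raises(AlignmentError, match="'J'"):
            Alignment([("a", "ACJDE")], "protein")

    def test_round_trip_identity(self, tmp_path, rng):
        tree = generate_yule_tree(6, 0.3, rng)
        aln, _ = simulate_alignment(tree, [("r", 50, 1.0)], rng, "protein")
        path = tmp_path / "roundtrip.fasta"
        write_fasta_alignment(aln, path)
        back = read_fasta_alignment(path, "protein")
        assert back.records == aln.records


class TestPDistance:
    def test_identical_sequences(self):
        aln = Alignment([("a", "AAAA" * 3), ("b", "AAAA" * 3)], "protein")
        assert p_distance(aln, "a", "b").p == 0.0

    def test_direct_mismatch_count(self):
        aln = Alignment([("a", "AAAAAAAAAAAA"), ("b", "AAASAAAAAAAS")], "protein")
        est = p_distance(aln, "a", "b")
        assert est.p == pytest.approx(2 / 12)
        assert est.n_sites == 12

    def test_pairwise_deletion_excludes_gaps_and_ambiguity(self):
        aln = Alignment([("a", "AA-AAAAAAAXA"), ("b", "AASAAAAAAASA")], "protein")
        est = p_distance(aln, "a", "b")
        assert est.n_sites == 10
        assert est.p == 0.0

    def test_insufficient_overlap(self):
        aln = Alignment([("a", "AAAA--------"), ("b", "----AAAAAAAA")], "protein")
        with pytest.raises(InsufficientOverlapError):
            p_distance(aln, "a", "b")


class TestCorrectDistance:
    @pytest.mark.parametrize("model", ["poisson", "jc20", "jc69"])
    def test_zero_p_gives_zero_distance(self, model):
        assert correct_distance(DistanceEstimate(p=0.0, n_sites=100), model) == 0.0

    def test_poisson_closed_form(self):
        d = correct_distance(DistanceEstimate(p=0.5, n_sites=100), "poisson")
        assert d == pytest.approx(math.log(2))

    def test_jc20_closed_form(self):
        d = correct_distance(DistanceEstimate(p=0.2, n_sites=100), "jc20")
        assert d == pytest.approx(-(19 / 20) * math.log(1 - (20 / 19) * 0.2))

    def test_jc69_saturation_capped_with_warning(self):
        est = DistanceEstimate(p=0.75 - 1e-9, n_sites=100)
        with pytest.warns(UserWarning, match="saturated"):
            d = correct_distance(est, "jc69")
        assert d == 5.0
        assert est.capped

    @pytest.mark.parametrize("model,bound", [("poisson", 1.0), ("jc20", 0.95), ("jc69", 0.75)])
    def test_monotone_in_p_below_saturation(self, model, bound):
        grid = np.linspace(0, bound * 0.98, 40)
        ds = [correct_distance(DistanceEstimate(p=float(p), n_sites=10), model) for p in grid]
        assert all(b >= a for a, b in zip(ds, ds[1:]))


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = Alignment([(f"s{i}", "ACDEFGHIKLMN") for i in range(3)], "protein")
        dm = distance_matrix(aln, "jc20")
        assert np.all(dm.values == 0)

    def test_matches_per_pair_composition(self, rng):
        tree = generate_yule_tree(5, 0.4, rng)
        aln, _ = simulate_alignment(tree, [("r", 200, 1.0)], rng, "protein")
        dm = distance_matrix(aln, "jc20")
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    expected = correct_distance(p_distance(aln, a, b), "jc20")
                    assert dm.values[i, j] == pytest.approx(expected)

    def test_invariant_under_record_reordering(self, rng):
        tree = generate_yule_tree(5, 0.3, rng)
        aln, _ = simulate_alignment(tree, [("r", 100, 1.0)], rng, "protein")
        shuffled = Alignment(list(reversed(aln.records)), "protein")
        dm1 = distance_matrix(aln, "jc20")
        dm2 = distance_matrix(shuffled, "jc20")
        for i, a in enumerate(dm1.labels):
            for b in dm1.labels[i + 1 :]:
                assert dm1.get(a, b) == pytest.approx(dm2.get(a, b))

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]]),
        )
        tree = neighbor_joining(dm)
        assert tree.patristic("a", "b") == pytest.approx(3.0)
        assert tree.patristic("a", "c") == pytest.approx(4.0)
        assert tree.patristic("b", "c") == pytest.approx(5.0)
        # the center branch lengths themselves: la=1, lb=2, lc=3
        lengths = {t: tree.nodes[tree.tip_id(t)].length for t in "abc"}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_matrix_recovers_tree(self, rng):
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(4, 16)))
            labels, mat = t.distance_matrix()
            nj = neighbor_joining(DistanceMatrix(labels, np.array(mat)))
            assert nj.bipartitions() == t.bipartitions()
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert abs(nj.patristic(a, b) - t.patristic(a, b)) < 1e-9

    def test_all_equal_distances_deterministic(self):
        n = 5
        labels = [f"t{i}" for i in range(n)]
        vals = np.ones((n, n)) - np.eye(n)
        t1 = neighbor_joining(DistanceMatrix(labels, vals))
        t2 = neighbor_joining(DistanceMatrix(labels, vals.copy()))
        from phyloconstraint.treeio import write_newick

        assert write_newick(t1) == write_newick(t2)

    def test_skbio_topology_cross_check(self, rng):
        """Our NJ topology matches scikit-bio's on a clean additive matrix."""
        import io

        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        t = random_tree(rng, 8)
        labels, mat = t.distance_matrix()
        ours = neighbor_joining(DistanceMatrix(labels, np.array(mat)))
        sk_tree = skbio_nj(SkbioDM(np.array(mat), ids=labels))
        from phyloconstraint.treeio import parse_newick

        sk = parse_newick(sk_tree.write(io.StringIO()).getvalue().strip())
        assert ours.bipartitions() == sk.bipartitions()

    def test_simulated_distances_converge_to_truth(self, rng):
        tree = generate_yule_tree(5, 0.2, rng)
        aln, _ = simulate_alignment(tree, [("r", 20000, 1.0)], rng, "protein")
        dm = distance_matrix(aln, "jc20")
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                true = tree.patristic(a, b)
                se = 3 * math.sqrt(max(true, 0.01) / 20000) * 3
                assert abs(dm.get(a, b) - true) < max(se, 0.02)
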