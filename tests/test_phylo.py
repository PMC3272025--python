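"""Phylogenetics: p-distance counting, NJ exactness on additive matrices,
agreement with scikit-bio's NJ on random metrics, bootstrap behaviour and
Newick round-trips."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from sinekit import consensus as cm
from sinekit import phylo
from sinekit import synthetic_data as sd
from sinekit.consensus import MultipleAlignment
from sinekit.seqcore import NucSequence, SequenceError

from conftest import random_seq


class TestPDistance:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment([("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTACGT")])
        dm = phylo.p_distance_matrix(msa)
        assert np.allclose(dm.data, 0.0)

    def test_counted_differences(self):
        msa = MultipleAlignment([("a", "AAAAAAAAAA"), ("b", "AAACCCAAAA"), ("c", "AAAAAAAAAA")])
        dm = phylo.p_distance_matrix(msa)
        assert dm["a", "b"] == pytest.approx(0.3)

    def test_gapped_pair_counts_shared_columns_only(self):
        msa = MultipleAlignment([("a", "AC-TA"), ("b", "ACG-A"), ("c", "ACGTA")])
        dm = phylo.p_distance_matrix(msa)
        # a/b share columns 1,2,5 -> 0 differences
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 0.0

    def test_all_gap_pair_rejected(self):
        msa = MultipleAlignment([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])
        with pytest.raises(SequenceError, match="a.*b|b.*a"):
            phylo.p_distance_matrix(msa)

    def test_bounds(self, rng):
        rows = [(f"t{i}", random_seq(rng, 60)) for i in range(5)]
        dm = phylo.p_distance_matrix(MultipleAlignment(rows))
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(np.diag(dm.data), 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ids=["a", "b", "c"])
        tree = phylo.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: la = (ab+ac-bc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(3.0)
        assert lengths["c"] == pytest.approx(5.0)

    def test_additive_four_taxon_topology_and_lengths(self):
        # built from the tree (A:1,B:2)-3-(C:1,D:2)
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 3], [6, 7, 3, 0]], ids=list("ABCD")
        )
        tree = phylo.neighbor_joining(dm)
        parts = phylo._bipartitions(tree)
        ab = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert parts == {ab}
        d = tree.tip_tip_distances()
        for i in "ABCD":
            for j in "ABCD":
                if i != j:
                    assert d[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    def test_label_permutation_same_topology(self, rng):
        n = 7
        pts = rng.random((n, 5))
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                m[i, j] = np.abs(pts[i] - pts[j]).sum()
        ids = [f"t{i}" for i in range(n)]
        t1 = phylo.neighbor_joining(DistanceMatrix(m, ids=ids))
        perm = list(rng.permutation(n))
        m2 = m[np.ix_(perm, perm)]
        t2 = phylo.neighbor_joining(DistanceMatrix(m2, ids=[ids[p] for p in perm]))
        assert phylo._bipartitions(t1) == phylo._bipartitions(t2)

    def test_matches_skbio_nj_topologies(self, rng):
        """Independent implementation check against scikit-bio's NJ."""
        for _ in range(5):
            n = 6
            pts = rng.random((n, 4))
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(n):
                    m[i, j] = np.abs(pts[i] - pts[j]).sum()
            dm = DistanceMatrix(m, ids=[f"t{i}" for i in range(n)])
            ours = phylo.neighbor_joining(dm)
            theirs = skbio_nj(dm)
            assert phylo._bipartitions(ours) == phylo._bipartitions(theirs)

    def test_asymmetric_matrix_rejected(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ids=list("abc"))
        dm.data[0, 1] = 5.0  # break symmetry behind the container's back
        with pytest.raises(SequenceError):
            phylo.neighbor_joining(dm)


def two_clade_msa(rng, n_per=4, within=0.02, between=0.20):
    anc = sd.make_consensus(sd.FamilySpec(name="anc"), 1)
    drift, _ = sd.mutate_copy(anc, between, 0.0, rng)
    copies = [NucSequence(f"A{i}", sd.mutate_copy(anc, within, 0.0, rng)[0]) for i in range(n_per)]
    copies += [NucSequence(f"B{i}", sd.mutate_copy(drift, within, 0.0, rng)[0]) for i in range(n_per)]
    return cm.star_msa(copies)


class TestBootstrap:
    def test_clean_split_high_support(self, rng):
        msa = two_clade_msa(rng)
        tree = phylo.bootstrap_support(msa, n_reps=100, seed=11)
        split_supports = [
            node.support
            for node in tree.non_tips(include_self=False)
            if {t.name for t in node.tips()} in ({f"A{i}" for i in range(4)}, {f"B{i}" for i in range(4)})
        ]
        assert split_supports and min(split_supports) >= 95

    def test_single_replicate_support_binary(self, rng):
        msa = two_clade_msa(rng)
        tree = phylo.bootstrap_support(msa, n_reps=1, seed=3)
        for node in tree.non_tips(include_self=False):
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_same_seed_reproducible(self, rng):
        msa = two_clade_msa(rng)
        t1 = phylo.bootstrap_support(msa, n_reps=25, seed=42)
        t2 = phylo.bootstrap_support(msa, n_reps=25, seed=42)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False) if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips(include_self=False) if n.support is not None)
        assert s1 == s2


class TestNewick:
    def test_three_leaf_format(self):
        dm = DistanceMatrix([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ids=["A", "B", "C"])
        nwk = phylo.write_newick(phylo.neighbor_joining(dm))
        assert nwk.endswith(";")
        assert set("ABC") <= set(nwk)
        reparsed = phylo.read_newick(nwk)
        assert {t.name for t in reparsed.tips()} == {"A", "B", "C"}

    def test_round_trip_preserves_distances(self, rng):
        n = 6
        pts = rng.random((n, 4))
        m = np.abs(pts[:, None, :] - pts[None, :, :]).sum(axis=2)
        dm = DistanceMatrix(m, ids=[f"t{i}" for i in range(n)])
        tree = phylo.neighbor_joining(dm)
        back = phylo.read_newick(phylo.write_newick(tree))
        d1, d2 = tree.tip_tip_distances(), back.tip_tip_distances()
        for i in range(n):
            for j in range(n):
                assert d1[f"t{i}", f"t{j}"] == pytest.approx(d2[f"t{i}", f"t{j}"], abs=1e-6)

    def test_low_supports_hidden(self, rng):
        msa = two_clade_msa(rng, n_per=3, within=0.12, between=0.15)
        tree = phylo.bootstrap_support(msa, n_reps=20, seed=9)
        nwk = phylo.write_newick(tree, include_support=True, min_support=50)
        shown = [
            n.support for n in tree.non_tips(include_self=False)
            if n.support is not None and n.support >= 50
        ]
        for s in shown:
            assert f"{s:g}" in nwk
        hidden = [
            n.support for n in tree.non_tips(include_self=False)
            if n.support is not None and n.support < 50
        ]
        # a hidden support value should not appear as an internal label
        for s in hidden:
            assert f"){s:g}:" not in nwk
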