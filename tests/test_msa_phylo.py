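"""Profile alignment, distances, NJ inference, rooting and clades."""

import math

import dendropy
import numpy as np
import pytest

from bacascan.io_formats import ProteinRecord
from bacascan.msa_phylo import (
    MSA,
    DistanceMatrix,
    align_to_profile,
    assign_clades,
    distance_matrix,
    flag_long_branches,
    nj_tree,
    root_tree,
    trim_columns,
    unrooted_splits,
)
from bacascan.profile_hmm import ProfileHMM


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestAlignToProfile:
    def test_consensus_aligns_gap_free(self, toy_hmm):
        cons = toy_hmm.consensus()
        msa = align_to_profile(toy_hmm, [ProteinRecord("c", cons)])
        assert msa.rows[0] == cons
        assert msa.width == toy_hmm.n_match

    def test_internal_insertion_dropped(self):
        # a model strongly favoring the match path; consensus with one
        # extra residue aligns to the identical match-column row
        me = np.full((4, 20), 1e-4)
        for k, aa in enumerate([10, 8, 17, 18]):  # M K V W
            me[k, aa] = 1.0
        me /= me.sum(axis=1, keepdims=True)
        tr = np.tile(np.array([0.90, 0.05, 0.05, 0.9, 0.1, 0.9, 0.1]), (4, 1))
        hmm = ProfileHMM("ins", me, tr)
        cons = hmm.consensus()
        assert cons == "MKVW"
        with_ins = cons[:2] + "A" + cons[2:]
        msa = align_to_profile(hmm, [ProteinRecord("a", with_ins), ProteinRecord("c", cons)])
        assert msa.rows[0] == cons
        assert msa.width == 4

    def test_unalignable_sequence_warns_all_gap_or_partial(self, toy_hmm):
        msa = align_to_profile(toy_hmm, [ProteinRecord("x", "X")])
        assert set(msa.rows[0]) <= set("X-")


class TestTrim:
    def test_all_gap_column_removed(self):
        msa = MSA(["a", "b"], ["A-C", "A-C"])
        assert trim_columns(msa, 0.99).rows == ["AC", "AC"]

    def test_hand_counted_gap_fractions(self):
        rows = ["ACDE", "AC-E", "A--E", "A---"]  # column gaps 0, .5, .75, .25
        msa = MSA(list("wxyz"), rows)
        out = trim_columns(msa, 0.5)
        assert out.width == 3  # the 0.75-gap column is dropped
        assert out.rows[0] == "ACE"

    def test_threshold_one_is_identity(self):
        msa = MSA(["a", "b"], ["A-", "-A"])
        assert trim_columns(msa, 1.0).rows == msa.rows

    def test_idempotent(self):
        msa = MSA(list("wxyz"), ["ACDE", "AC-E", "A--E", "A---"])
        once = trim_columns(msa, 0.5)
        assert trim_columns(once, 0.5).rows == once.rows

    def test_nothing_left_is_error(self):
        msa = MSA(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError):
            trim_columns(msa, 0.4)


class TestDistances:
    def test_identical_rows_zero(self):
        dm = distance_matrix(MSA(["a", "b"], ["MKVL", "MKVL"]))
        assert dm.d[0, 1] == 0.0

    def test_poisson_correction_half(self):
        dm = distance_matrix(MSA(["a", "b"], ["MKVL", "MKAA"]))
        assert dm.d[0, 1] == pytest.approx(math.log(2))

    def test_saturation_cap(self):
        dm = distance_matrix(MSA(["a", "b"], ["MKVL", "ACDE"]))
        assert dm.d[0, 1] == pytest.approx(-math.log(0.05))

    def test_no_shared_columns_warns(self):
        with pytest.warns(UserWarning, match="no alignment columns"):
            dm = distance_matrix(MSA(["a", "b", "c"], ["MK--", "--VL", "MKVL"]))
        assert dm.d[0, 1] == dm.d.max()


def _additive_distances(tree: dendropy.Tree) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], d)


def _random_tree(rng: np.random.Generator, n: int) -> dendropy.Tree:
    import random as _random

    from dendropy.simulate import treesim

    t = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=_random.Random(int(rng.integers(2**31))),
    )
    for i, lf in enumerate(t.leaf_node_iter()):
        lf.taxon.label = f"L{i}"
    for e in t.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.uniform(0.1, 1.0))
    return t


class TestNeighborJoining:
    def test_three_taxon_exact(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.0]]))
        t = nj_tree(dm)
        lens = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lens == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_recovers_additive_topology(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            src = _random_tree(rng, 8)
            dm = _additive_distances(src)
            out = nj_tree(dm)
            assert unrooted_splits(out) == unrooted_splits(src)

    def test_matches_reference_nj_on_random_matrices(self):
        # independent cross-check against scikit-bio's implementation
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(9)
        for _ in range(10):
            src = _random_tree(rng, 7)
            dm = _additive_distances(src)
            ours = nj_tree(dm)
            sk_newick = str(skbio_nj(SkbioDM(dm.d, ids=dm.ids)))
            sk_tree = dendropy.Tree.get(data=sk_newick, schema="newick")
            assert unrooted_splits(ours) == unrooted_splits(sk_tree)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(10)
        src = _random_tree(rng, 8)
        dm = _additive_distances(src)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix([dm.ids[i] for i in perm], dm.d[np.ix_(perm, perm)])
        assert unrooted_splits(nj_tree(dm)) == unrooted_splits(nj_tree(dm2))

    def test_branch_lengths_nonnegative(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            d = rng.uniform(0.1, 2.0, (n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            t = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], d))
            for e in t.preorder_edge_iter():
                if e.length is not None:
                    assert e.length >= 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestRooting:
    def test_single_leaf_outgroup_bisects_terminal_branch(self):
        t = _tree("((A:1,B:1):1,(C:1,D:4):1);")
        rooted = root_tree(t, {"D"})
        kids = rooted.seed_node.child_nodes()
        sides = [sorted(lf.taxon.label for lf in k.leaf_iter()) for k in kids]
        assert ["D"] in sides
        d_edge = next(k for k in kids if [lf.taxon.label for lf in k.leaf_iter()] == ["D"])
        assert d_edge.edge.length == pytest.approx(2.0)

    def test_outgroup_clade_rooting(self):
        t = _tree("((A:1,B:1):1,((C:1,D:1):1,(E:1,F:1):1):1);")
        rooted = root_tree(t, {"E", "F"})
        sides = [
            frozenset(lf.taxon.label for lf in k.leaf_iter())
            for k in rooted.seed_node.child_nodes()
        ]
        assert frozenset({"E", "F"}) in sides

    def test_outgroup_everything_warns(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.warns(UserWarning, match="whole tree"):
            root_tree(t, {"A", "B", "C", "D"})

    def test_rooting_preserves_unrooted_splits(self):
        rng = np.random.default_rng(12)
        src = _random_tree(rng, 8)
        labels = sorted(lf.taxon.label for lf in src.leaf_node_iter())
        rooted = root_tree(src, set(labels[:2]))
        assert unrooted_splits(rooted) == unrooted_splits(src)

    def test_empty_outgroup_rejected(self):
        with pytest.raises(ValueError):
            root_tree(_tree("(A:1,B:1,C:1);"), set())


class TestClades:
    def _setup(self):
        t = _tree(
            "(((((p1:1,p4:1):1,(p5:1,p6:1):1):1,((p2:1,p3:1):1,p7:1):1):1,p8:3):1,p9:4);"
        )
        t.is_rooted = True
        comps = [["p4", "p5", "p6", "p7"], ["p2", "p3"], ["p1"], ["p8"], ["p9"]]
        labels = {
            "p1": "BacA", "p2": "BclA", "p3": "BclA", "p4": "MBacA",
            "p5": "BclA", "p6": "BclA", "p7": "BclA", "p8": "BclA", "p9": "ExsE",
        }
        return t, comps, labels

    def test_reference_layout_clades(self):
        # mirrors the layout of the nine experimentally characterized
        # proteins: the core cluster + BacA cluster span clade C, the
        # remaining ingroup leaf is clade B, the ExsE leaf is clade A
        t, comps, labels = self._setup()
        ca = assign_clades(t, comps, labels)
        assert {p: c for p, c in ca.clade.items() if c == "A"} == {"p9": "A"}
        assert ca.clade["p8"] == "B"
        assert all(ca.clade[f"p{i}"] == "C" for i in range(1, 8))

    def test_partition_complete(self):
        t, comps, labels = self._setup()
        ca = assign_clades(t, comps, labels)
        assert set(ca.clade) == {f"p{i}" for i in range(1, 10)}
        assert set(ca.clade.values()) <= {"A", "B", "C", "unassigned"}

    def test_ingroup_single_component_leaves_clade_b_empty(self):
        t = _tree("(((p1:1,p2:1):1,(p3:1,p4:1):1):1,p9:4);")
        t.is_rooted = True
        comps = [["p1", "p2", "p3", "p4"], ["p9"]]
        labels = {"p1": "BacA", "p2": "BacA", "p3": "BclA", "p4": "BclA", "p9": "Brady"}
        ca = assign_clades(t, comps, labels)
        assert sorted(v for v in ca.clade.values()) == ["A", "C", "C", "C", "C"]

    def test_no_outgroup_warns_unassigned(self):
        t = _tree("((p1:1,p2:1):1,(p3:1,p4:1):1);")
        t.is_rooted = True
        with pytest.warns(UserWarning, match="outgroup"):
            ca = assign_clades(t, [["p1", "p2"]], {"p1": "BacA", "p2": "BacA"})
        assert set(ca.clade.values()) == {"unassigned"}


class TestLongBranches:
    def test_equal_terminals_no_flags(self):
        t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert not any(flag_long_branches(t, 5.0).values())

    def test_single_long_terminal_flagged(self):
        t = _tree("((A:1,B:1):1,(C:1,D:10):1);")
        flags = flag_long_branches(t, 5.0)
        assert flags == {"A": False, "B": False, "C": False, "D": True}

    def test_huge_multiplier_no_flags(self):
        t = _tree("((A:1,B:1):1,(C:1,D:10):1);")
        assert not any(flag_long_branches(t, 1e9).values())
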