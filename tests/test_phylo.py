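"""Distances, neighbor joining, rooting, bootstrap."""

import dendropy
import numpy as np
import pytest

from genefamkit import phylo, simulate as sg
from genefamkit.alignments import CodonAlignment


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        a = CodonAlignment(["x", "y"], ["ATGGCTAAA" * 12] * 2)
        _, D, _ = phylo.pairwise_distance(a)
        assert D[0, 1] == 0

    def test_jc_closed_form(self):
        # p = 0.1 -> d = -(3/4) ln(1 - 4*0.1/3) = 0.10732...
        base = "A" * 120
        other = "C" * 12 + "A" * 108
        a = CodonAlignment(["x", "y"], [base, other])
        _, D, _ = phylo.pairwise_distance(a, "jc_nucleotide")
        assert D[0, 1] == pytest.approx(0.1073256, abs=1e-6)
        _, Dp, _ = phylo.pairwise_distance(a, "p_distance")
        assert Dp[0, 1] == pytest.approx(0.1)

    def test_matches_site_loop_with_pairwise_deletion(self, rng):
        for _ in range(10):
            rows = []
            for _r in range(2):
                chars = rng.choice(list("ACGT-"), size=60,
                                   p=[0.22, 0.22, 0.22, 0.22, 0.12])
                rows.append("".join(chars))
            a = CodonAlignment(["x", "y"], rows)
            try:
                _, D, _ = phylo.pairwise_distance(a, "p_distance")
            except ValueError:
                continue
            diff = tot = 0
            for c1, c2 in zip(*rows):
                if c1 in "ACGT" and c2 in "ACGT":
                    tot += 1
                    diff += c1 != c2
            assert D[0, 1] == pytest.approx(diff / tot)

    def test_saturated_pair_hits_ceiling(self):
        a = CodonAlignment(["x", "y"], ["ATG" * 20, "GCA" * 20])
        with pytest.warns(UserWarning, match="saturated"):
            _, D, sat = phylo.pairwise_distance(a)
        assert sat == [("x", "y")]
        assert D[0, 1] == phylo.SATURATION_CEILING


def additive_matrix_from_tree(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], D


def random_tree(n_taxa, rng):
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=taxa, rng=rng)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length, 0.05)
    tree.is_rooted = False
    return tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        ids = ["a", "b", "c"]
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]])
        tree = phylo.nj_tree(ids, D)
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_additive_eight_taxon_tree(self):
        import random
        tree = random_tree(8, random.Random(5))
        ids, D = additive_matrix_from_tree(tree)
        assert phylo.rf_distance(phylo.nj_tree(ids, D), tree) == 0

    def test_additivity_property_many_trees(self):
        """NJ must exactly recover the generating topology from additive
        distances (50 random trees, 5-12 taxa)."""
        import random
        pyrng = random.Random(11)
        for k in range(50):
            tree = random_tree(pyrng.randint(5, 12), pyrng)
            ids, D = additive_matrix_from_tree(tree)
            assert phylo.rf_distance(phylo.nj_tree(ids, D), tree) == 0

    def test_taxon_order_invariance(self, rng):
        import random
        tree = random_tree(7, random.Random(3))
        ids, D = additive_matrix_from_tree(tree)
        base = phylo.nj_tree(ids, D)
        perm = rng.permutation(len(ids))
        tree2 = phylo.nj_tree([ids[i] for i in perm], D[np.ix_(perm, perm)])
        assert phylo.rf_distance(base, tree2) == 0

    def test_agrees_with_independent_nj(self):
        """Cross-check against scikit-bio's neighbor joining."""
        import random
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        for seed in (1, 2, 3):
            tree = random_tree(6, random.Random(seed))
            ids, D = additive_matrix_from_tree(tree)
            ours = phylo.nj_tree(ids, D)
            theirs = skbio_nj(DistanceMatrix(D, ids))
            theirs_dp = phylo.read_newick(str(theirs).strip())
            assert phylo.rf_distance(ours, theirs_dp) == 0

    def test_rejects_asymmetric_matrix(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(["a", "b", "c"], D)


class TestRooting:
    def test_root_on_outgroup_pendant_branch(self):
        tree = phylo.read_newick("((a:1,b:1):1,(c:1,og:3):1);")
        rooted = phylo.root_with_outgroup(tree, ["og"])
        kids = rooted.seed_node.child_nodes()
        sides = [{lf.taxon.label for lf in k.leaf_iter()} for k in kids]
        assert {"og"} in sides

    def test_prune_flag_removes_outgroup(self):
        tree = phylo.read_newick("((a:1,b:1):1,(c:1,og:3):1);")
        rooted = phylo.root_with_outgroup(tree, ["og"], prune_outgroup=True)
        assert sorted(lf.taxon.label for lf in rooted.leaf_node_iter()) == \
            ["a", "b", "c"]

    def test_non_monophyletic_outgroup_raises(self):
        tree = phylo.read_newick("((a:1,og1:1):1,(og2:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="not monophyletic"):
            phylo.root_with_outgroup(tree, ["og1", "og2"])

    def test_rooting_preserves_unrooted_topology(self):
        nwk = "((a:1,b:1):1,(c:1,(d:1,og:2):1):1);"
        tree = phylo.read_newick(nwk)
        rooted = phylo.root_with_outgroup(tree, ["og"])
        assert phylo.rf_distance(rooted, phylo.read_newick(nwk)) == 0


class TestNewickRoundtrip:
    def test_emitted_newick_reparses_identically(self):
        import random
        for seed in range(5):
            tree = random_tree(6, random.Random(seed))
            text = phylo.write_newick(tree)
            again = phylo.read_newick(text)
            assert phylo.rf_distance(tree, again) == 0


class TestBootstrap:
    def _structured_alignment(self, n_codons=1000, seed=0):
        tree = phylo.read_newick(
            "(((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.4):0.01,"
            "(E:0.05,F:0.05):0.01);", rooted=True)
        return sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=n_codons, seed=seed))

    def test_deep_split_gets_high_support(self):
        aln = self._structured_alignment()
        tree = phylo.bootstrap_support(aln, n_replicates=100, seed=1)
        # find the branch separating {A,B} (or {C,D}) from the rest
        supports = {}
        for node in tree.preorder_internal_node_iter():
            clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
            supports[clade] = getattr(node, "support", None)
        ab = supports.get(frozenset("AB")) or supports.get(frozenset("CDEF"))
        assert ab is not None and ab >= 95

    def test_fixed_seed_reproducible(self):
        aln = self._structured_alignment(n_codons=200)
        t1 = phylo.bootstrap_support(aln, n_replicates=20, seed=7)
        t2 = phylo.bootstrap_support(aln, n_replicates=20, seed=7)
        s1 = sorted(n.support for n in t1.preorder_internal_node_iter()
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.preorder_internal_node_iter()
                    if hasattr(n, "support"))
        assert s1 == s2
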