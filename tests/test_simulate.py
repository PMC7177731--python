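"""Gene-family, codon, and droplet simulators against their ground truth."""

import math

import numpy as np
import pytest

from genefamkit import simulate as sg
from genefamkit.phylo import read_newick, rf_distance


def n_leaves(tree):
    return sg.count_extant_genes(tree)


class TestGeneTreeSimulation:
    def test_no_event_limit_reproduces_species_tree(self, four_taxon_spec):
        tree, log = sg.simulate_gene_tree(four_taxon_spec,
                                          sg.FamilySimParams(seed=3))
        assert sorted(lf.taxon.label for lf in tree.leaf_node_iter()) == \
            ["A_g1", "B_g1", "C_g1", "D_g1"]
        assert {r.event for r in log.records} == {"speciation"}
        # topology congruent with the species tree
        sp = four_taxon_spec.tree()
        for lf in sp.leaf_node_iter():
            lf.taxon.label += "_g1"
        assert rf_distance(tree, sp) == 0

    def test_deterministic_wgd_retention(self):
        spec = sg.SpeciesTreeSpec("(A:1,B:1):1;",
                                  [sg.WGDEvent("N0", 0.5, 1.0, 2)])
        tree, log = sg.simulate_gene_tree(spec, sg.FamilySimParams(seed=11))
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        assert labels == ["A_g1", "A_g2", "B_g1", "B_g2"]
        assert log.count("wgd_retention") == 1
        assert log.count("loss") == 0

    def test_triplication_with_full_retention(self):
        spec = sg.SpeciesTreeSpec("(A:1,B:1):1;",
                                  [sg.WGDEvent("N0", 0.5, 1.0, 3)])
        tree, _ = sg.simulate_gene_tree(spec, sg.FamilySimParams(seed=11))
        assert n_leaves(tree) == 6  # multiplicity exactly multiplies copies

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg.FamilySimParams(birth_rate=-1)
        with pytest.raises(ValueError):
            sg.WGDEvent("N0", 0.5, 1.0, 4)
        with pytest.raises(ValueError):
            sg.WGDEvent("N0", 1.5, 1.0, 2)

    def test_birth_death_expectation_on_single_branch(self):
        """Mean surviving copy number after time t from one ancestor is
        e^((lambda-mu) t); checked within 3 standard errors over 5,000
        replicates on a branch with lambda > mu."""
        lam, mu, t = 0.6, 0.2, 1.0
        spec = sg.SpeciesTreeSpec(f"(A:{t},B:0.0);")
        counts = []
        for seed in range(5000):
            tree, _ = sg.simulate_gene_tree(
                spec, sg.FamilySimParams(birth_rate=lam, death_rate=mu,
                                         seed=seed))
            counts.append(sum(1 for lf in tree.leaf_node_iter()
                              if lf.taxon.label.startswith("A_")))
        counts = np.asarray(counts, dtype=float)
        expected = math.exp((lam - mu) * t)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_event_count_conservation(self, four_taxon_spec):
        """Survivor bookkeeping: per-species gene counts follow from one
        root lineage plus surviving duplication events minus losses that
        reach the present; here asserted as tree-vs-log consistency."""
        for seed in range(30):
            tree, log = sg.simulate_gene_tree(
                four_taxon_spec,
                sg.FamilySimParams(birth_rate=0.3, death_rate=0.15,
                                   tandem_fraction=0.3, seed=seed))
            internal = [n for n in tree.preorder_node_iter()
                        if not n.is_leaf() and n.label]
            labelled = {r.node_id for r in log.records if r.node_id}
            # every surviving internal node is logged exactly once
            assert {n.label for n in internal} == labelled
            assert len(labelled) == len(
                [r for r in log.records if r.node_id])
            # binary tree identity: leaves = internal nodes + 1
            if n_leaves(tree):
                assert n_leaves(tree) == len(internal) + 1

    def test_extinct_family_returns_empty_tree(self):
        spec = sg.SpeciesTreeSpec("(A:1,B:1);")
        tree, log = sg.simulate_gene_tree(
            spec, sg.FamilySimParams(birth_rate=0.0, death_rate=50.0, seed=0))
        assert n_leaves(tree) == 0
        assert log.n_losses >= 1
        assert all(r.event == "loss" for r in log.records)


class TestCodonSimulation:
    def test_zero_branch_lengths_give_identical_sequences(self, four_taxon_spec):
        tree, _ = sg.simulate_gene_tree(four_taxon_spec, sg.FamilySimParams(seed=1))
        for node in tree.preorder_node_iter():
            node.edge.length = 0.0
        aln = sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=50, seed=4))
        assert len(set(aln.rows)) == 1

    def test_rejects_negative_branch_lengths(self, four_taxon_spec):
        tree, _ = sg.simulate_gene_tree(four_taxon_spec, sg.FamilySimParams(seed=1))
        next(tree.leaf_node_iter()).edge.length = -0.1
        with pytest.raises(ValueError, match="negative"):
            sg.simulate_codon_alignment(tree, sg.CodonSimParams())

    def test_no_stop_codons_and_classes_recorded(self, six_taxon_tree):
        aln = sg.simulate_codon_alignment(
            six_taxon_tree, sg.CodonSimParams(alignment_length=120, seed=9,
                                              omega2=5.0,
                                              foreground_branches={"N1"}))
        assert aln.codon_state_matrix().min() >= 0  # gap-free, no stops
        classes = aln.meta["site_classes"]
        assert set(classes) <= {"0", "1", "2a", "2b"}
        assert len(classes) == 120

    def test_neutral_regime_calibrates_kaks_near_one(self):
        """A two-taxon alignment simulated entirely at omega = 1 should give
        NG86 Ka/Ks near 1 in at least 90% of replicates. The calibration is
        run at kappa = 1 because the NG86 estimator itself assumes no
        transition/transversion bias (under kappa > 1 it is known to be
        biased below 1)."""
        from genefamkit.kaks import ng86_kaks
        tree = read_newick("(X:0.2,Y:0.2);", rooted=True)
        ok = 0
        for seed in range(100):
            aln = sg.simulate_codon_alignment(
                tree, sg.CodonSimParams(alignment_length=2000, omega0=1.0,
                                        kappa=1.0, p0=0.0, p1=1.0, seed=seed))
            r = ng86_kaks(aln.rows[0], aln.rows[1])
            ok += 0.85 <= r.ratio <= 1.15
        assert ok >= 90

    def test_kappa_raises_transition_fraction(self):
        """At equal divergence, kappa = 8 must give a strictly higher
        transition share among observed differences than kappa = 1."""
        tree = read_newick("(X:0.3,Y:0.3);", rooted=True)
        purines = set("AG")

        def transition_fraction(aln):
            a, b = aln.rows
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            ts = sum((x in purines) == (y in purines) for x, y in diffs)
            return ts / len(diffs)

        wins = 0
        for seed in range(50):
            f8 = transition_fraction(sg.simulate_codon_alignment(
                tree, sg.CodonSimParams(alignment_length=500, kappa=8.0,
                                        seed=seed)))
            f1 = transition_fraction(sg.simulate_codon_alignment(
                tree, sg.CodonSimParams(alignment_length=500, kappa=1.0,
                                        seed=seed)))
            wins += f8 > f1
        assert wins == 50


class TestDroplets:
    def test_zero_concentration_all_negative(self):
        a = sg.simulate_droplets(1000, 0.0, seed=0)
        assert a.n_negative == a.n_total == 1000

    def test_ln2_gives_half_negative(self):
        n = 17_000
        a = sg.simulate_droplets(n, math.log(2), seed=123)
        se = math.sqrt(0.25 / n)
        assert abs(a.negative_fraction - 0.5) < 3 * se

    def test_rejects_negative_lambda(self):
        with pytest.raises(ValueError):
            sg.simulate_droplets(100, -0.1)


class TestBundleEmission:
    def test_roundtrip_bytes(self, tmp_path, four_taxon_spec):
        tree, log = sg.simulate_gene_tree(four_taxon_spec,
                                          sg.FamilySimParams(seed=5))
        aln = sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=60, seed=5))
        paths = sg.emit_family_bundle(tree, aln, sg.StructureSpec("GS1"),
                                      tmp_path / "fam", event_log=log)
        back = sg.read_family_bundle(tmp_path / "fam")
        for sid in aln.ids:
            assert back["cds"][sid] == aln.ungapped(sid)
        assert rf_distance(back["tree"], tree) == 0
        assert len(back["events"]) == len(log.records)
        # refuses silent overwrite
        with pytest.raises(FileExistsError):
            sg.emit_family_bundle(tree, aln, sg.StructureSpec("GS1"),
                                  tmp_path / "fam", event_log=log)

    def test_gs1_preset_emits_12_exons(self, tmp_path, four_taxon_spec):
        tree, _ = sg.simulate_gene_tree(four_taxon_spec, sg.FamilySimParams(seed=5))
        aln = sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=120, seed=5))
        sg.emit_family_bundle(tree, aln, sg.StructureSpec("GS1"),
                              tmp_path / "fam")
        from genefamkit.genomics import read_gff3_genes
        genes = read_gff3_genes(tmp_path / "fam" / "genes.gff3")
        counts = [g.exon_count for regions in genes.values() for g in regions]
        assert counts and all(c == 12 for c in counts)

    def test_empty_family_warns(self, tmp_path):
        import dendropy
        from genefamkit.alignments import CodonAlignment
        with pytest.warns(UserWarning, match="empty family"):
            sg.emit_family_bundle(dendropy.Tree(), CodonAlignment([], []),
                                  sg.StructureSpec("GS2"), tmp_path / "empty")
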