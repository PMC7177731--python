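"""Region stats, gene structures, microsynteny chaining, in-silico PCR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genefamkit import genomics as gn


class TestRegionStats:
    def test_gc_percent(self):
        r = gn.RegionAnnotation("r", sequence="ATGC")
        assert gn.region_stats(r)["gc_percent"] == 50.0

    def test_ambiguity_codes_excluded(self):
        r = gn.RegionAnnotation("r", sequence="ATGCNNNN")
        assert gn.region_stats(r)["gc_percent"] == 50.0

    def test_repeat_fraction(self):
        r = gn.RegionAnnotation("r", length=1000,
                                repeat_intervals=[(100, 150, "Ty1/Copia")])
        s = gn.region_stats(r)
        assert s["repeat_percent"] == 5.0 and s["repeat_bp"] == 50

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            gn.region_stats(gn.RegionAnnotation("r", sequence="", length=0))

    @given(st.lists(st.tuples(st.integers(0, 990), st.integers(1, 200)),
                    max_size=30))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_merged_repeat_bp_matches_per_base_scan(self, raw):
        intervals = [(s, min(1000, s + ln), "x") for s, ln in raw]
        r = gn.RegionAnnotation("r", length=1000, repeat_intervals=intervals)
        covered = np.zeros(1000, dtype=bool)
        for s, e, _ in intervals:
            covered[s:e] = True
        assert gn.region_stats(r)["repeat_bp"] == int(covered.sum())

    def test_interval_order_invariance(self, rng):
        intervals = [(int(s), int(s) + 50, "x")
                     for s in rng.integers(0, 900, size=10)]
        r1 = gn.RegionAnnotation("r", length=1000, repeat_intervals=intervals)
        r2 = gn.RegionAnnotation("r", length=1000,
                                 repeat_intervals=intervals[::-1])
        assert gn.region_stats(r1)["repeat_bp"] == \
            gn.region_stats(r2)["repeat_bp"]


class TestFamilySummary:
    def test_single_region_identity(self):
        s = gn.region_stats(gn.RegionAnnotation(
            "only", sequence="ATGC" * 100,
            repeat_intervals=[(0, 40, "x")]))
        out = gn.summarize_family_regions([s], "fam")
        assert out["mean_gc_percent"] == 50.0
        assert out["max_repeat_region"] == "only"
        assert out["min_repeat_percent"] == out["max_repeat_percent"] == 10.0


class TestGeneStructures:
    def test_protein_lengths_from_cds(self):
        genes = [gn.GeneFeature("GS2a1", exons=[(1, 1299)], cds_length=1299),
                 gn.GeneFeature("PEPC5", exons=[(1, 3135)], cds_length=3135)]
        table, _ = gn.gene_structure_summary(genes)
        by_gene = table.set_index("gene")["protein_length_aa"]
        assert by_gene["GS2a1"] == 432
        assert by_gene["PEPC5"] == 1044

    def test_protein_identity_invariant(self, rng):
        genes = [gn.GeneFeature(f"g{i}", exons=[(1, 3 * n)], cds_length=3 * n)
                 for i, n in enumerate(rng.integers(100, 500, size=10))]
        table, _ = gn.gene_structure_summary(genes)
        assert (3 * (table.protein_length_aa + 1) ==
                table.cds_length_bp).all()

    def test_exon_count_mode(self):
        genes = [gn.GeneFeature(f"g{i}", exons=[(1, 10)] * n, cds_length=30)
                 for i, n in enumerate([12, 12, 12, 13])]
        _, mode = gn.gene_structure_summary(genes)
        assert mode == 12

    def test_tied_modes_reported_as_list(self):
        genes = [gn.GeneFeature(f"g{i}", exons=[(1, 10)] * n, cds_length=30)
                 for i, n in enumerate([12, 12, 13, 13])]
        _, mode = gn.gene_structure_summary(genes)
        assert mode == [12, 13]

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError, match="divisible"):
            gn.gene_structure_summary(
                [gn.GeneFeature("bad", exons=[(1, 100)], cds_length=100)])


class TestMicrosynteny:
    def test_forward_block(self):
        anchors = [gn.SyntenyAnchor(i, i) for i in (1, 2, 3)]
        blocks = gn.microsynteny_chain(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "forward" and len(blocks[0]) == 3

    def test_inversion_block(self):
        anchors = [gn.SyntenyAnchor(1, 3), gn.SyntenyAnchor(2, 2),
                   gn.SyntenyAnchor(3, 1)]
        blocks = gn.microsynteny_chain(anchors)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted" and len(blocks[0]) == 3

    def test_block_monotonicity_invariant(self, rng):
        anchors = [gn.SyntenyAnchor(int(a), int(b))
                   for a, b in rng.integers(0, 50, size=(60, 2))]
        dedup = {(a.a_index, a.b_index): a for a in anchors}
        for block in gn.microsynteny_chain(list(dedup.values())):
            xs = [a.a_index for a in block.anchors]
            ys = [a.b_index for a in block.anchors]
            assert xs == sorted(xs)
            if block.orientation == "forward":
                assert ys == sorted(ys)
            else:
                assert ys == sorted(ys, reverse=True)

    def test_planted_diagonal_recovered_among_noise(self):
        """A 6-anchor diagonal planted in 40 random noise anchors is
        recovered at default parameters in >= 95 of 100 seeds."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            planted = {(10 + k, 30 + k) for k in range(6)}
            noise = set()
            while len(noise) < 40:
                a, b = (int(x) for x in rng.integers(0, 100, size=2))
                if (a, b) not in planted:
                    noise.add((a, b))
            anchors = [gn.SyntenyAnchor(a, b) for a, b in
                       sorted(planted | noise)]
            blocks = gn.microsynteny_chain(anchors)
            found = any(planted <= {(x.a_index, x.b_index)
                                    for x in b.anchors} for b in blocks)
            hits += found
        assert hits >= 95

    def test_min_block_discards_short_chains(self):
        anchors = [gn.SyntenyAnchor(1, 1), gn.SyntenyAnchor(2, 2)]
        assert gn.microsynteny_chain(anchors, min_block=3) == []


class TestInsilicoPcr:
    FWD = "GTTGGTCCCTCTGTTGGAAT"
    REV = "ATAAGCAGCAATGTGCTCAT"

    def _template(self, rng, spacer=100):
        middle = "".join(rng.choice(list("ACGT"), size=spacer))
        return "A" * 17 + self.FWD + middle + \
            gn.reverse_complement(self.REV) + "G" * 11

    def test_constructed_product_length(self, rng):
        tpl = self._template(rng)
        products = gn.insilico_pcr(tpl, self.FWD, self.REV)
        assert len(products) == 1
        assert products[0][2] == 20 + 100 + 20

    def test_no_reverse_match_empty(self, rng):
        tpl = "A" * 10 + self.FWD + "C" * 50
        assert gn.insilico_pcr(tpl, self.FWD, self.REV) == []

    def test_two_forward_sites_two_products(self, rng):
        mid = "".join(rng.choice(list("ACGT"), size=40))
        tpl = self.FWD + mid + self.FWD + mid + \
            gn.reverse_complement(self.REV)
        products = gn.insilico_pcr(tpl, self.FWD, self.REV)
        assert len(products) == 2
        assert products == sorted(products)

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            gn.insilico_pcr("ACGT" * 30, "ACGT", self.REV)

    def test_published_primer_pair_amplifies_synthetic_template(self, rng):
        """The packaged GS primer pair yields its printed product length on a
        synthetic template built to match (571 bp product)."""
        from genefamkit.pipeline import load_primer_table
        primers = load_primer_table()
        row = primers[primers.probe == "GS"].iloc[0]
        f, r = row.forward_primer, row.reverse_primer
        inner = int(row.product_length_bp) - len(f) - len(r)
        tpl = "T" * 33 + f + "".join(rng.choice(list("ACGT"), size=inner)) \
            + gn.reverse_complement(r) + "C" * 21
        products = gn.insilico_pcr(tpl, f, r)
        assert [p[2] for p in products] == [int(row.product_length_bp)]
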