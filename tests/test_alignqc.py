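"""Gap-pattern QC, trimming, back-translation, and clade masking."""

import numpy as np
import pytest

from genefamkit import alignqc as qc
from genefamkit.alignments import CodonAlignment


def aln_from(rows, prefix="s"):
    return CodonAlignment([f"{prefix}{i}" for i in range(len(rows))], rows)


class TestGapDistance:
    def test_identical_patterns_zero(self):
        a = aln_from(["ATG---", "CCC---", "GGG---"])
        D = qc.gap_distance_matrix(a)
        assert np.all(D == 0)

    def test_definition_example(self):
        # masks 001100... vs 000000... differ at two columns
        a = aln_from(["AT--TAGGG", "ATGCTAGGG"])
        D = qc.gap_distance_matrix(a)
        assert D[0, 1] == 2

    def test_matches_double_loop(self, rng):
        rows = []
        for _ in range(20):
            mask = rng.random(99) < 0.2
            rows.append("".join("-" if m else "A" for m in mask))
        a = aln_from(rows)
        D = qc.gap_distance_matrix(a)
        gaps = a.gap_mask()
        for i in range(20):
            for j in range(20):
                assert D[i, j] == np.sum(gaps[i] != gaps[j])


class TestOutliers:
    def test_uniform_gap_patterns_flag_nothing(self):
        a = aln_from(["ATG---CCC"] * 10)
        assert qc.flag_gap_outliers(a) == []

    def test_heavily_gapped_row_is_flagged(self):
        clean = "ATG" * 100
        dirty = "---" * 40 + "ATG" * 60
        a = aln_from([clean] * 9 + [dirty])
        assert qc.flag_gap_outliers(a) == ["s9"]

    def test_null_flag_rate_below_ten_percent(self):
        """Exchangeable random gap masks: the mean+z*sd rule should flag
        rarely (z = 2.5 corresponds to ~1% two-sided under normality)."""
        flagged = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = ["".join("-" if x else "A" for x in rng.random(60) < 0.3)
                    for _ in range(12)]
            flagged += len(qc.flag_gap_outliers(aln_from(rows)))
            total += 12
        assert flagged / total <= 0.10

    def test_permutation_invariance(self, rng):
        rows = ["".join("-" if x else "A" for x in rng.random(60) < 0.3)
                for _ in range(10)]
        rows[3] = "-" * 60  # one genuine outlier
        a = aln_from(rows)
        base = set(qc.flag_gap_outliers(a))
        order = rng.permutation(10)
        b = CodonAlignment([a.ids[i] for i in order],
                           [a.rows[i] for i in order])
        assert set(qc.flag_gap_outliers(b)) == base

    def test_too_few_sequences_warns(self):
        with pytest.warns(UserWarning):
            assert qc.flag_gap_outliers(aln_from(["ATG", "AT-", "A--"])) == []


class TestTrimByOccupancy:
    def test_examples(self):
        # one codon column occupied in 6 of 10 rows: dropped at 0.70
        rows = ["ATGCCC"] * 6 + ["---CCC"] * 4
        out = qc.trim_by_occupancy(aln_from(rows), 0.70)
        assert out.n_codons == 1
        assert out.rows[0] == "CCC"
        # all-gap codon column removed at any threshold
        rows = ["---AAA", "---TTT"]
        assert qc.trim_by_occupancy(aln_from(rows), 0.01).n_codons == 1

    def test_matches_brute_force(self, rng):
        rows = []
        for _ in range(8):
            rows.append("".join("---" if rng.random() < 0.4 else "ATG"
                                for _ in range(30)))
        a = aln_from(rows)
        out = qc.trim_by_occupancy(a, 0.5)
        keep = [j for j in range(30)
                if sum(r[3 * j:3 * j + 3] != "---" for r in rows) / 8 >= 0.5]
        assert out.n_codons == len(keep)
        for i, r in enumerate(rows):
            assert out.rows[i] == "".join(r[3 * j:3 * j + 3] for j in keep)

    def test_fully_trimmed_raises(self):
        with pytest.raises(ValueError, match="fully trimmed"):
            qc.trim_by_occupancy(aln_from(["---", "---"]), 0.5)

    def test_trim_nesting_property(self, rng):
        rows = ["".join("---" if rng.random() < 0.4 else "GCT"
                        for _ in range(40)) for _ in range(10)]
        a = aln_from(rows)
        direct = qc.trim_by_occupancy(a, 0.7)
        staged = qc.trim_by_occupancy(qc.trim_by_occupancy(a, 0.3), 0.7)
        assert staged.rows == direct.rows


class TestMaskRareCodonColumns:
    def test_strict_less_than_boundary(self):
        # 10 clade members; column occupied in 2 (0.2 -> removed) vs 3
        # (0.3 -> retained: the rule is strictly "less than")
        rows2 = ["ATGAAA"] * 2 + ["---AAA"] * 8
        rows3 = ["ATGAAA"] * 3 + ["---AAA"] * 7
        a2, a3 = aln_from(rows2), aln_from(rows3)
        clade = [f"s{i}" for i in range(10)]
        assert qc.mask_rare_codon_columns(a2, clade).n_codons == 1
        assert qc.mask_rare_codon_columns(a3, clade).n_codons == 2

    def test_scoped_to_clade(self):
        rows = ["ATGAAA"] * 2 + ["---AAA"] * 8
        a = aln_from(rows)
        # within the first three rows the column has occupancy 2/3
        out = qc.mask_rare_codon_columns(a, ["s0", "s1", "s2"])
        assert out.n_codons == 2

    def test_matches_brute_force(self, rng):
        rows = ["".join("---" if rng.random() < 0.5 else "CGT"
                        for _ in range(25)) for _ in range(12)]
        a = aln_from(rows)
        clade = [f"s{i}" for i in range(5)]
        out = qc.mask_rare_codon_columns(a, clade, 0.4)
        keep = [j for j in range(25)
                if sum(rows[i][3 * j:3 * j + 3] != "---"
                       for i in range(5)) / 5 >= 0.4]
        assert out.n_codons == len(keep)

    def test_empty_clade_raises(self):
        with pytest.raises(ValueError):
            qc.mask_rare_codon_columns(aln_from(["ATG"]), [])


class TestBacktranslate:
    def test_definition_example(self):
        out = qc.backtranslate({"x": "M-A"}, {"x": "ATGGCT"})
        assert out.row("x") == "ATG---GCT"

    def test_terminal_stop_stripped(self):
        out = qc.backtranslate({"x": "MA"}, {"x": "ATGGCTTAA"})
        assert out.row("x") == "ATGGCT"

    def test_internal_stop_and_mismatch_errors(self):
        with pytest.raises(ValueError, match="internal stop"):
            qc.backtranslate({"x": "MXA"}, {"x": "ATGTAAGCT"})
        with pytest.raises(ValueError, match="residue 2"):
            qc.backtranslate({"x": "MK"}, {"x": "ATGGCT"})

    def test_roundtrip_translation(self, rng):
        from genefamkit import codonmodel as cm
        codons = [c for c in cm.CODONS if cm.translate_codon(c) != "M"]
        prots, cdss = {}, {}
        for k in range(5):
            picked = ["ATG"] + [codons[i] for i in
                                rng.integers(0, len(codons), size=20)]
            cdss[f"p{k}"] = "".join(picked)
            aa = "".join(cm.translate_codon(c) for c in picked)
            # scatter some gaps
            gapped = list(aa)
            for pos in rng.integers(0, len(gapped), size=4):
                gapped.insert(int(pos), "-")
            prots[f"p{k}"] = "".join(gapped)
        out = qc.backtranslate(prots, cdss)
        for k in prots:
            ungapped = out.ungapped(k)
            assert ungapped == cdss[k]
            back = "".join(cm.translate_codon(ungapped[i:i + 3])
                           for i in range(0, len(ungapped), 3))
            assert back == prots[k].replace("-", "")
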