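"""Alignment QC: back-translate a protein alignment to codons, trim
low-occupancy columns, and flag gap-pattern outliers.
"""

from genefamkit import alignqc

# a protein alignment and its unaligned coding sequences (the third CDS
# carries a terminal stop codon, which is stripped with a log message)
proteins = {"seq1": "MKL-A", "seq2": "MKLQA", "seq3": "M--QA"}
cds = {"seq1": "ATGAAACTTGCT", "seq2": "ATGAAGCTCCAAGCA",
       "seq3": "ATGCAGGCGTGA"}

codon_aln = alignqc.backtranslate(proteins, cds)
print("back-translated codon alignment:")
for sid in codon_aln.ids:
    print(f"  {sid}: {codon_aln.row(sid)}")

trimmed = alignqc.trim_by_occupancy(codon_aln, min_occupancy=0.70)
print(f"\n70% occupancy trim: {codon_aln.n_codons} -> {trimmed.n_codons} "
      "codon columns (columns gapped in more than 30% of rows removed)")

# outlier detection needs a few more rows; plant one heavily gapped sequence
rows = ["ATGGCTAAAGGG"] * 7 + ["---------GGG"]
from genefamkit.alignments import CodonAlignment
aln = CodonAlignment([f"s{i}" for i in range(8)], rows)
flagged = alignqc.flag_gap_outliers(aln)
print(f"\ngap-pattern outliers among 8 sequences: {flagged} "
      "(the truncated row; such rows are usually partial gene models)")
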