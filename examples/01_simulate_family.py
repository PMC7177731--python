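"""Simulate a gene family along a species tree with a whole-genome
duplication, and write the bundle to disk.

The species tree has a WGD (retention 0.8) on the branch above the (A,B)
ancestor, so most families should carry an extra gene copy in A and B.
"""

from tempfile import mkdtemp

from genefamkit import simulate as sg
from genefamkit.phylo import write_newick

species = sg.SpeciesTreeSpec(
    "((A:1,B:1):0.5,(C:1,D:0.8):0.7);",
    wgd_events=[sg.WGDEvent(branch="N1", time_fraction=0.5,
                            retention=0.8, multiplicity=2)])

tree, log = sg.simulate_gene_tree(
    species, sg.FamilySimParams(birth_rate=0.05, death_rate=0.02,
                                tandem_fraction=0.2, seed=42))

print("gene tree:", write_newick(tree).strip())
print(f"{sg.count_extant_genes(tree)} surviving gene copies")
print("\nevent log (speciations, duplications, losses with their "
      "species-tree branch):")
print(log.to_frame().to_string(index=False))

aln = sg.simulate_codon_alignment(
    tree, sg.CodonSimParams(alignment_length=300, seed=42))
out = mkdtemp(prefix="family_")
sg.emit_family_bundle(tree, aln, sg.StructureSpec("GS1"), out, event_log=log)
print(f"\nwrote CDS/protein FASTA, GFF3 (12-exon preset), Newick and the "
      f"event log to {out}")
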