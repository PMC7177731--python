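"""Selection-pressure scan: pairwise Ka/Ks and the branch-site likelihood
ratio test of episodic positive selection.

Data are simulated with omega2 = 8 acting on 15% of sites along one
foreground branch, so the LRT should reject the null and the naive
empirical Bayes posteriors should point at the truly selected sites.
"""

from genefamkit import branchsite as bs, kaks, phylo, simulate as sg

tree = phylo.read_newick(
    "(((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15):0.1,(E:0.3,F:0.3):0.1);",
    rooted=True)
sg.ensure_node_labels(tree)

aln = sg.simulate_codon_alignment(
    tree, sg.CodonSimParams(alignment_length=400, omega0=0.2, omega2=8.0,
                            p0=0.57, p1=0.28, foreground_branches={"N1"},
                            seed=5))

table = kaks.kaks_pair_table(aln, [("A", "B"), ("C", "D"), ("E", "F")])
print("pairwise NG86 Ka/Ks (sister pairs):")
print(table[["seq1", "seq2", "ka", "ks", "ratio", "classification"]]
      .round(3).to_string(index=False))

out = bs.branch_site_test(tree, aln, foreground="N1", seed=1)
print(f"\nbranch-site LRT on foreground N1: 2*dlnL = {out.statistic:.2f}, "
      f"p = {out.p_value:.2e} (chi-square, 1 df)")
print(f"alternative model MLEs: omega2 = {out.alt_model.omega2:.2f}, "
      f"p2 = {1 - out.alt_model.p0 - out.alt_model.p1:.3f}")
if out.neb_sites:
    print("NEB sites with posterior >= 0.95 (codon index, posterior):")
    for i, p in out.neb_sites[:10]:
        print(f"  site {i}: {p:.3f}")
print("\nsmall p-values indicate episodic positive selection on the "
      "foreground branch; the pairwise ratios stay < 1 because most sites "
      "remain under purifying selection.")
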