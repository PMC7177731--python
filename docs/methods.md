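# Methods

This note records the models behind genefamkit, the defaults that matter,
what the simulators do and do not emulate, and the numerical choices made
where the design was open.

## Gene-family simulator

Gene families evolve along a rooted binary species tree (branch lengths in
arbitrary time units) under a linear birth–death process: each gene lineage
independently duplicates at rate λ (events/lineage/time) and dies at rate μ,
sampled by Gillespie waiting times per lineage. A configurable fraction of
births is labelled *tandem*; the label only changes the event-log annotation
(no genomic coordinates are simulated) and is consumed by the
duplication-timing classifier. Whole-genome duplications are placed on a
named branch at a fractional position; at the event every lineage alive is
copied to the stated multiplicity (2 = duplication, 3 = triplication — both
are supported because either scenario can explain an observed genome
triplication) and each copy survives independently with the retention
probability. Retention 1 therefore multiplies the extant copy number exactly
by the multiplicity, and retention 0.8 with low background rates produces
the "WGD-era duplication burst" used in the recovery tests. Extinct
subtrees are pruned; events whose node is suppressed by pruning stay in the
log with an empty node id, so the log remains a complete history while the
tree stays strictly binary.

Default study conditions in the calibration suites: a four-taxon species
tree `((A:1,B:1):0.5,(C:1,D:0.8):0.7)` with λ = 0.05, μ = 0.02, tandem
fraction 0.2, and (where a WGD is involved) retention 0.8 at the midpoint of
the internal branch above (A,B). These rates keep families in the realistic
1–3 copies-per-species range reported for small metabolic gene families.

## Codon model

One GY94-style engine serves both simulation and inference: a 61-state
(universal code, stops excluded) reversible rate matrix with
`q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for single-nucleotide
changes. Matrices are scaled so the *background site-class mixture* has mean
rate 1, putting branch lengths in expected substitutions per codon; the
simulator and the likelihood engine share this convention, so simulated
branch lengths can be passed to inference unchanged. Transition
probabilities come from a symmetric eigendecomposition (exact for
reversible matrices and much cheaper than repeated `expm` calls); the
pruning algorithm is vectorised over sites with per-node rescaling against
underflow.

Site-class structure follows branch-site "model A": classes 0 (ω₀ < 1
everywhere), 1 (ω = 1 everywhere), 2a (ω₀ background / ω₂ foreground), and
2b (1 background / ω₂ foreground), with p2a : p2b = p0 : p1. The simulator
draws true site classes from the same structure, records them, and they
anchor the NEB-precision checks.

## Branch-site LRT

Null (ω₂ = 1) and alternative (ω₂ ≥ 1 free) models are fitted by bounded
L-BFGS-B on transformed parameters (log κ, logit ω₀, stick-breaking logits
for p₀/p₁, log(ω₂ − 1)), convergence at 1e-8 on lnL. Branch lengths are
taken as given and fixed for both hypotheses (they are estimated upstream
or, for simulated data, known); a global scale can be optimised instead via
the engine API. Codon frequencies default to F3x4 estimated from the
alignment with a 0.1 pseudocount; an equal-frequency option exists for
exact-oracle tests.

The alternative-model likelihood surface has a known degenerate corner
(p₀ = p₁ = 0: every site in class 2 with a modest ω₂), which a single
warm start can fall into. The fit therefore uses three structured starts —
the null optimum with ω₂ = 2, the null optimum with ω₂ = 8, and a generic
interior point with ω₂ = 4 — and keeps the best; additional randomized
starts are available via `n_starts`. This replaces naive repeated cold
starts: it targets the failure mode directly at a third of the cost.
On occasional datasets the corner (or near-corner) fit is the genuine MLE;
its site posterior then assigns essentially every site to class 2 and
carries no site-level information, so the NEB site list is suppressed
(flagged `degenerate_site_posterior`) whenever the fitted class-2
proportion reaches 0.9 — the significance call itself is unaffected.
2ΔlnL is clamped at 0 and referred to χ² with 1 df (the plain df-1 test,
not the 50:50 mixture refinement), which makes the test conservative:
calibrated type-I error lands near 0.02–0.04 at α = 0.05. Positively
selected sites are reported by naive empirical Bayes (posterior of classes
2a+2b at the alternative MLEs, threshold 0.95) only when the test is
significant; Bayes empirical Bayes is out of scope. No multiple-testing
correction is applied by default across branch tests (per-test α
reporting); a Benjamini–Hochberg helper is provided.

Calibration problem sizes: type-I error on a six-taxon tree with 300 codons
(200 replicates in the test suite; 100 in the acceptance script's quicker
pass), power at ω₂ = 8, p₂ = 0.15, 500 codons (100 and 50 replicates
respectively). These sizes put Monte-Carlo error comfortably inside the
asserted bands.

## Ka/Ks (NG86)

Nei–Gojobori (1986) counting: per-codon synonymous site fractions computed
over non-stop single-nucleotide changes (renormalised, so every codon
contributes exactly 3 sites and N + S = 3 × codons), pathway averaging over
all orderings of multi-nucleotide differences excluding stop-crossing paths
(falling back to all paths only when every one is blocked), Jukes–Cantor
correction of pN and pS, saturation flagged at p ≥ 0.75. The estimator
assumes no transition/transversion bias; its neutral calibration
(ratio ≈ 1 at ω = 1) is therefore run at κ = 1 — under κ > 1 NG86 is
biased downward, a property of the estimator, not an implementation issue.
Classification bands (purifying < 0.5, neutral 0.5–1.5, positive > 1.5) are
reporting conventions, configurable; they place the conventional "neutral"
example value 0.87 in the neutral band.

## Reconciliation

Duplication/loss-only LCA reconciliation on rooted binary trees with unit
costs (configurable): node *g* is a duplication iff its species mapping
equals that of a child; losses per gene edge (p→c) follow the
depth-difference rule — `d(M(p), M(c)) − 1` for a speciation parent,
`d(M(p), M(c))` for a duplication parent — attributed to the off-path
sibling branches so per-branch loss tables can be reported. Horizontal
transfer is deliberately not modelled. For rooted binary inputs this is the
unique minimum-cost reconciliation; the test suite verifies cost-equality
against exhaustive enumeration over all valid mappings for ~1.3k small gene
trees. Input polytomies are resolved to caterpillars in deterministic
smallest-leaf-label order and flagged. Timing classification labels each
duplication with its mapped species branch (leaf branch →
"lineage-specific", named internal branches → their clade name), optionally
gated on ≥ 90% support of the subtending gene-tree branch.

## Clustering

MCL is implemented densely: self-loops weighted by each node's maximum
incident edge weight (stabilises attractors), expansion = matrix square,
inflation = elementwise power then column renormalisation, pruning floor
1e-6, convergence at max column change < 1e-8 within 200 iterations;
columns that prune to zero park their mass on the node itself. Clusters are
read from attractor overlap components. Inflation is selected by averaged
silhouette width (scikit-learn `silhouette_samples` on the bounded distance
`d = 1 − w/cap`, non-adjacent pairs at d = 1); candidates yielding fewer
than 2 or as many clusters as nodes are skipped as undefined, and ties
break toward the smallest inflation (coarsest clustering). The default
candidate set {1.2, 1.4, 2.0, 4.0, 6.0} brackets the conventional optimum
of 1.4 for protein-family graphs.

## Trees

Saitou–Nei NJ with deterministic tie-breaking (lexicographic smallest
descendant-leaf label pairs) and negative branch lengths clamped to zero
with a warning. Distances are pairwise-deletion p or Jukes–Cantor
(`d = −(3/4) ln(1 − 4p/3)`), requiring ≥ 30 overlapping ungapped sites, with
saturated pairs (p ≥ 0.75) set to a 5.0 substitutions/site ceiling.
Nonparametric bootstrap resamples codon columns. NJ is exact on additive
matrices (property-tested over random trees, and cross-checked against
scikit-bio's independent implementation); it is a desk-scale stand-in for
ML tree search, which is out of scope — externally computed Newick trees
are accepted anywhere a tree is an input.

## ddPCR

λ = −ln(n_neg/n_total) copies per droplet; the 95% CI propagates the
binomial error of the negative fraction through the log transform
(`se = sqrt((1 − f)/(n f))`). All-positive assays raise a saturation error
(the estimator diverges; dilution is the remedy); all-negative assays
return λ = 0 with a one-sided bound. Copy number is the ratio of target to
reference λ times the reference copy count, with a delta-method CI on the
log scale combining both assays' relative errors. Simulated assays use
17,000 droplets, the typical partition count of a 20 µL reaction.

## What the simulators do not emulate

Intron/intergenic sequence, repeat sequence, recombination, codon-usage
bias beyond π, rate heterogeneity beyond the discrete site classes,
alignment error (the simulator emits true alignments), and search-engine
artefacts (pipeline "hits" on simulated data are derived from sequence
identity). Passing tests therefore demonstrate correctness of the
statistical machinery under its own model assumptions, not robustness to
real-data violations such as misalignment or assembly error — the QC
operations exist precisely because real inputs have those problems.

## Known limitations

- The branch-site test's χ²₁ reference makes it conservative; power figures
  are specific to the simulated tree shape and divergence.
- NG86 is biased under strong transition/transversion bias or extreme codon
  frequencies; the likelihood machinery is the remedy when that matters.
- Reconciliation assumes the gene tree is correct; tree uncertainty enters
  only through the optional support gating.
- The degenerate corner of model A is handled by structured starts, not by
  a reparameterisation; pathological alignments could still require more
  starts (`n_starts`).
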