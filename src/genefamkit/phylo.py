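"""Desk-scale tree building: pairwise distances, neighbor joining, outgroup
rooting, and nonparametric bootstrap support.

Trees are :class:`dendropy.Tree` objects throughout. Externally computed
Newick trees are accepted anywhere a tree is an input; the NJ machinery here
exists so the reconciliation and selection stages can be exercised end-to-end
on simulated data without an external search engine.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .alignments import CodonAlignment

SATURATION_CEILING = 5.0  # substitutions/site assigned to saturated pairs


# ---------------------------------------------------------------------------
# Newick helpers
# ---------------------------------------------------------------------------

def read_newick(source: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal string."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    kwargs = {}
    if rooted is not None:
        kwargs["rooting"] = "force-rooted" if rooted else "force-unrooted"
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True, **kwargs)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    b = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pairwise_distance(aln: CodonAlignment, model: str = "jc_nucleotide",
                      min_overlap: int = 30,
                      ceiling: float = SATURATION_CEILING):
    """Pairwise-deletion nucleotide distances.

    ``model`` is ``p_distance`` (raw proportion of differing sites) or
    ``jc_nucleotide`` (Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3)).
    Saturated pairs (p >= 0.75 under JC) are set to ``ceiling`` and flagged.

    Returns (ids, matrix, saturated_pairs).
    """
    if model not in ("p_distance", "jc_nucleotide"):
        raise ValueError(f"unknown model {model!r}")
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    chars = aln.char_matrix()
    valid = np.isin(chars, list("ACGT"))
    n = aln.n_sequences
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            overlap = int(both.sum())
            if overlap < min_overlap:
                raise ValueError(
                    f"pair ({aln.ids[i]}, {aln.ids[j]}): only {overlap} "
                    f"overlapping ungapped sites (< {min_overlap})")
            p = float((chars[i, both] != chars[j, both]).mean())
            if model == "p_distance":
                d = p
            elif p >= 0.75:
                warnings.warn(f"saturated pair ({aln.ids[i]}, {aln.ids[j]}): "
                              f"p={p:.3f}; distance set to ceiling")
                saturated.append((aln.ids[i], aln.ids[j]))
                d = ceiling
            else:
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return list(aln.ids), D, saturated


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(ids: Sequence[str], D: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (representative, representative) label pair, where a merged node is
    represented by its smallest descendant leaf label. Negative branch
    lengths are clamped to zero with a warning. The returned tree is
    unrooted (trifurcating root node).
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for label in ids:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=label)
        nodes.append(node)
    reps = list(ids)  # representative label per active node
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i != j}
    next_idx = n

    def d(i, j):
        return dist[(i, j)]

    def clamp(x, what):
        if x < 0:
            warnings.warn(f"negative branch length {x:.4g} for {what} clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for a_pos, i in enumerate(active):
            for j in active[a_pos + 1:]:
                q = (m - 2) * d(i, j) - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = clamp(0.5 * d(i, j) + (r[i] - r[j]) / (2 * (m - 2)), reps[i])
        lj = clamp(d(i, j) - li, reps[j])
        lj = clamp(lj, reps[j])
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(u, k)] = dist[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = clamp(0.5 * (d(i, j) + d(i, k) - d(j, k)), reps[i])
    lj = clamp(0.5 * (d(i, j) + d(j, k) - d(i, k)), reps[j])
    lk = clamp(0.5 * (d(i, k) + d(j, k) - d(i, j)), reps[k])
    root = tree.seed_node
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = ln
        root.add_child(node)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: dendropy.Tree, outgroup_labels: Iterable[str],
                       prune_outgroup: bool = False) -> dendropy.Tree:
    """Root on the branch subtending a monophyletic outgroup.

    With ``prune_outgroup`` the outgroup leaves are removed after rooting
    (so reconciliation sees only the ingroup) while the root placement is
    retained.
    """
    outgroup = set(outgroup_labels)
    tree = tree.clone(depth=1)
    labels = set(leaf_labels(tree))
    missing = outgroup - labels
    if missing:
        raise ValueError(f"outgroup labels absent from tree: {sorted(missing)}")
    tree.encode_bipartitions()
    target = None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        clade = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        if clade == outgroup or (labels - clade) == outgroup:
            target = edge
            break
    if target is None:
        # report which leaves break monophyly: those inside the smallest
        # clade containing the outgroup but not in the outgroup
        best = labels
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            clade = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
            for side in (clade, labels - clade):
                if outgroup <= side and len(side) < len(best):
                    best = side
        raise ValueError("outgroup is not monophyletic; conflicting leaves: "
                         f"{sorted(best - outgroup)}")
    length = target.length or 0.0
    tree.reroot_at_edge(target, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    if prune_outgroup:
        tree.prune_taxa_with_labels(sorted(outgroup))
        # pruning can leave a unifurcate root; keep the root but collapse it
        tree.suppress_unifurcations()
        tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: CodonAlignment, n_replicates: int = 100,
                      seed: int = 0, model: str = "jc_nucleotide",
                      min_overlap: int = 30) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap support on internal branches.

    Codon columns are resampled with replacement; each replicate alignment is
    rebuilt with the same distance model and NJ, and every internal branch of
    the reference tree is annotated (``node.label`` and ``node.support``)
    with the percentage of replicates containing that bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ids, D, _ = pairwise_distance(aln, model=model, min_overlap=min_overlap)
    ref = nj_tree(ids, D)
    ref.encode_bipartitions()

    counts: dict[int, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_codons, size=aln.n_codons)
        rep_aln = aln.select_codon_columns(cols)
        try:
            rep_ids, rep_D, _ = pairwise_distance(rep_aln, model=model,
                                                  min_overlap=min_overlap)
        except ValueError:
            continue  # replicate lost all overlap for some pair
        rep = dendropy.Tree.get(data=write_newick(nj_tree(rep_ids, rep_D)),
                                schema="newick",
                                taxon_namespace=ref.taxon_namespace,
                                preserve_underscores=True)
        rep.encode_bipartitions()
        for bp in rep.bipartition_encoding:
            counts[bp.split_bitmask] = counts.get(bp.split_bitmask, 0) + 1

    for node in ref.preorder_node_iter():
        if node.is_leaf() or node is ref.seed_node:
            continue
        pct = 100.0 * counts.get(node.edge.bipartition.split_bitmask, 0) / n_replicates
        node.support = pct
        node.label = f"{pct:.0f}"
    return ref
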