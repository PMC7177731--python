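"""Gene-tree / species-tree reconciliation under duplication-loss parsimony.

The last-common-ancestor (LCA) mapping assigns every gene-tree node to the
species-tree LCA of the species of its descendant genes. A node is a
duplication iff it maps to the same species node as one of its children;
losses are counted from the depth gaps along mapped paths (the classic
depth-difference rule: for gene edge p -> c the number of losses is
d(M(p), M(c)) - 1 if p is a speciation and d(M(p), M(c)) if p is a
duplication, d being the number of species-tree edges between the mapped
nodes). For rooted binary inputs this mapping is the unique minimum of
c_dup * D + c_loss * L. Horizontal transfer is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy

from .simulate import ensure_node_labels, _node_id


@dataclass
class ReconciliationResult:
    """Events and costs of one reconciliation."""

    events: dict           # gene node label -> "speciation" | "duplication"
    mapping: dict          # gene node label -> species node/leaf label
    losses_per_branch: dict  # species branch label -> loss count
    duplications: int
    losses: int
    c_dup: float = 1.0
    c_loss: float = 1.0
    flags: list = field(default_factory=list)

    @property
    def cost(self) -> float:
        return self.c_dup * self.duplications + self.c_loss * self.losses


def read_leaf_map(path) -> dict[str, str]:
    """Two-column TSV (gene_id, species) -> leaf map dict."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "species"], dtype=str)
    return dict(zip(df.gene_id, df.species))


def _check_rooted_binary(tree: dendropy.Tree, name: str) -> None:
    seed = tree.seed_node
    if seed is None or len(seed.child_nodes()) != 2:
        raise ValueError(
            f"{name} must be rooted with a binary root; root it first "
            "(phylo.root_with_outgroup)")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and len(node.child_nodes()) != 2:
            raise ValueError(f"{name} contains a polytomy; resolve it first "
                             "(reconcile.resolve_polytomies)")


def resolve_polytomies(tree: dendropy.Tree) -> tuple[dendropy.Tree, bool]:
    """Resolve polytomies into caterpillars in deterministic label order.

    Returns (tree, was_modified). The caterpillar is built over children
    sorted by their smallest descendant leaf label, so the resolution is
    reproducible for any input ordering.
    """
    tree = tree.clone(depth=1)
    modified = False

    def min_leaf(node):
        return min(lf.taxon.label for lf in node.leaf_iter())

    for node in list(tree.preorder_node_iter()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        modified = True
        kids = sorted(kids, key=min_leaf)
        for k in kids:
            node.remove_child(k)
        current = kids[0]
        for nxt in kids[1:-1]:
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(current)
            joint.add_child(nxt)
            current = joint
        node.add_child(current)
        node.add_child(kids[-1])
    return tree, modified


def lca_reconcile(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                  leaf_map: Mapping[str, str], c_dup: float = 1.0,
                  c_loss: float = 1.0) -> ReconciliationResult:
    """Minimum duplication-loss reconciliation by LCA mapping."""
    _check_rooted_binary(gene_tree, "gene tree")
    _check_rooted_binary(species_tree, "species tree")
    ensure_node_labels(species_tree)
    ensure_node_labels(gene_tree)

    sp_leaf = {lf.taxon.label: lf for lf in species_tree.leaf_node_iter()}
    depth, parent = {}, {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1

    def lca(a, b):
        while depth[a] > depth[b]:
            a = parent[a]
        while depth[b] > depth[a]:
            b = parent[b]
        while a is not b:
            a, b = parent[a], parent[b]
        return a

    for leaf in gene_tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in leaf_map:
            raise ValueError(f"gene leaf {label!r} missing from leaf map")
        if leaf_map[label] not in sp_leaf:
            raise ValueError(f"species {leaf_map[label]!r} absent from "
                             "species tree")

    M, events = {}, {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            M[node] = sp_leaf[leaf_map[node.taxon.label]]
            continue
        left, right = node.child_nodes()
        M[node] = lca(M[left], M[right])
        is_dup = M[node] is M[left] or M[node] is M[right]
        events[_node_id(node)] = "duplication" if is_dup else "speciation"

    losses_per_branch: dict[str, int] = {}
    total_losses = 0
    for node in gene_tree.preorder_node_iter():
        p = node.parent_node
        if p is None:
            continue
        # walk from M(node) up to M(p); each passed species node contributes
        # a loss on its off-path child branch
        chain = []
        s = M[node]
        while s is not M[p]:
            chain.append(s)
            s = parent[s]
            if s is None:
                raise AssertionError("LCA mapping violated ancestry")
        p_is_dup = events.get(_node_id(p)) == "duplication"
        # speciation parent: the step out of M(p) itself is explained by the
        # speciation; duplication parent: every step is a potential loss
        steps = chain if p_is_dup else chain[:-1]
        for s in steps:
            sib = [c for c in parent[s].child_nodes() if c is not s]
            branch = _node_id(sib[0]) if sib else _node_id(parent[s])
            losses_per_branch[branch] = losses_per_branch.get(branch, 0) + 1
            total_losses += 1

    D = sum(1 for e in events.values() if e == "duplication")
    return ReconciliationResult(
        events=events,
        mapping={(_node_id(g)): _node_id(m) for g, m in M.items()},
        losses_per_branch=losses_per_branch,
        duplications=D, losses=total_losses, c_dup=c_dup, c_loss=c_loss)


def choose_reconstruction(candidates: Sequence[ReconciliationResult]) -> int:
    """Index of the minimum-cost candidate; ties broken by fewer
    duplications, then input order."""
    if not candidates:
        raise ValueError("no candidates")
    best = 0
    for i, cand in enumerate(candidates[1:], start=1):
        ref = candidates[best]
        if (cand.cost, cand.duplications) < (ref.cost, ref.duplications):
            best = i
    return best


def classify_duplication_timing(result: ReconciliationResult,
                                species_tree: dendropy.Tree,
                                clade_labels: Mapping[str, str] | None = None,
                                tandem_flags: Mapping[str, bool] | None = None,
                                gene_tree: dendropy.Tree | None = None,
                                min_support: float | None = None) -> list[dict]:
    """Label each duplication with the species-tree branch it maps to.

    Leaf branches give "lineage-specific"; named internal branches (via
    ``clade_labels``, e.g. {"N3": "ancestral-legume"}) give that name; other
    internal branches keep their branch label. ``tandem_flags`` (from
    synteny or a simulation event log) are propagated. With ``min_support``
    and a support-annotated gene tree, only duplications whose subtending
    branch reaches the threshold are reported (well-supported-clade gating).
    """
    clade_labels = dict(clade_labels or {})
    tandem_flags = dict(tandem_flags or {})
    sp_leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}

    support = {}
    if gene_tree is not None:
        for node in gene_tree.preorder_node_iter():
            if node.is_leaf():
                continue
            s = getattr(node, "support", None)
            if s is None and node.label:
                try:
                    s = float(node.label)
                except ValueError:
                    s = None
            if s is not None:
                support[_node_id(node)] = float(s)

    rows = []
    for node_label, event in result.events.items():
        if event != "duplication":
            continue
        if min_support is not None:
            s = support.get(node_label)
            if s is None or s < min_support:
                continue
        branch = result.mapping[node_label]
        if branch in sp_leaves:
            timing = "lineage-specific"
        else:
            timing = clade_labels.get(branch, branch)
        rows.append({"node": node_label, "species_branch": branch,
                     "label": timing,
                     "tandem": bool(tandem_flags.get(node_label, False))})
    return rows
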