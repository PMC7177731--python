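"""Independent brute-force oracles used by the test suite and the acceptance
script. These deliberately avoid the implementation paths they check: the
reconciliation oracle enumerates every valid mapping, the Ka/Ks oracle
recounts sites and pathway differences with Biopython's translator, and the
likelihood oracle sums over all internal-node states with scipy's expm.
"""

from __future__ import annotations

from itertools import permutations, product

import numpy as np
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# Reconciliation: exhaustive minimum over all valid mappings
# ---------------------------------------------------------------------------

def brute_force_min_dl(gene_tree, species_tree, leaf_map):
    """Minimum duplications + losses over every valid gene->species mapping.

    Trees are dendropy rooted binary trees. Returns (cost, D, L) of the
    optimum. A mapping assigns each internal gene node a species node that is
    an ancestor-or-self of its children's assignments; the event of a node is
    a speciation iff its two children map into distinct child subtrees of the
    node's species; losses on the edge p->c equal the depth gap minus one for
    a speciation parent and the full depth gap for a duplication parent.
    """
    sp_parent, sp_depth = {}, {}
    for node in species_tree.preorder_node_iter():
        sp_parent[node] = node.parent_node
        sp_depth[node] = 0 if node.parent_node is None else \
            sp_depth[node.parent_node] + 1

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = sp_parent[node]
        return out

    def is_ancestor_or_self(a, b):
        """a ancestor-or-self of b."""
        while b is not None:
            if b is a:
                return True
            b = sp_parent[b]
        return False

    sp_leaves = {lf.taxon.label: lf for lf in species_tree.leaf_node_iter()}
    gene_nodes = list(gene_tree.postorder_node_iter())
    internal = [g for g in gene_nodes if not g.is_leaf()]
    fixed = {g: sp_leaves[leaf_map[g.taxon.label]]
             for g in gene_nodes if g.is_leaf()}

    def lca(a, b):
        anc = set(id(x) for x in ancestors(a))
        while b is not None:
            if id(b) in anc:
                return b
            b = sp_parent[b]
        raise AssertionError

    # candidate assignments: ancestors-or-self of the LCA of descendants
    lca_of = {}
    for g in gene_nodes:
        if g.is_leaf():
            lca_of[g] = fixed[g]
        else:
            l, r = g.child_nodes()
            lca_of[g] = lca(lca_of[l], lca_of[r])
    candidates = {g: ancestors(lca_of[g]) for g in internal}

    best = None
    for combo in product(*(candidates[g] for g in internal)):
        M = dict(fixed)
        M.update(dict(zip(internal, combo)))
        ok = True
        for g in internal:
            for c in g.child_nodes():
                if not is_ancestor_or_self(M[g], M[c]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        D = L = 0
        events = {}
        for g in internal:
            l, r = g.child_nodes()
            if M[g] is not M[l] and M[g] is not M[r]:
                # which child subtrees of M[g] do they fall in?
                kids = M[g].child_nodes()
                side_l = next(k for k in kids if is_ancestor_or_self(k, M[l]))
                side_r = next(k for k in kids if is_ancestor_or_self(k, M[r]))
                events[g] = "spec" if side_l is not side_r else "dup"
            else:
                events[g] = "dup"
            if events[g] == "dup":
                D += 1
        for g in gene_nodes:
            p = g.parent_node
            if p is None:
                continue
            gap = sp_depth[M[g]] - sp_depth[M[p]]
            L += gap if events[p] == "dup" else gap - 1
        cost = D + L
        if best is None or cost < best[0]:
            best = (cost, D, L)
    return best


def enumerate_rooted_topologies(leaves):
    """All rooted binary tree shapes over the given leaf label list,
    as nested tuples."""
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    first, rest = leaves[0], leaves[1:]
    # distribute: first leaf goes left with every non-empty subset of rest
    n = len(rest)
    for mask in range(2 ** n):
        left = [first] + [rest[i] for i in range(n) if mask >> i & 1]
        right = [rest[i] for i in range(n) if not (mask >> i & 1)]
        if not right:
            continue
        for lt in enumerate_rooted_topologies(left):
            for rt in enumerate_rooted_topologies(right):
                out.append((lt, rt))
    # deduplicate mirror images
    seen, uniq = set(), []
    for t in out:
        key = _canon(t)
        if key not in seen:
            seen.add(key)
            uniq.append(t)
    return uniq


def _canon(t):
    if isinstance(t, str):
        return t
    a, b = _canon(t[0]), _canon(t[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def topology_to_newick(t):
    if isinstance(t, str):
        return t
    return f"({topology_to_newick(t[0])},{topology_to_newick(t[1])})"


# ---------------------------------------------------------------------------
# NG86 counting oracle (Biopython translator, explicit loops)
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


from functools import lru_cache


@lru_cache(maxsize=None)
def _aa(codon):
    return str(Seq(codon).translate())


def ng86_counts_oracle(seq1: str, seq2: str):
    """(N, S, Nd, Sd) recomputed from first principles."""
    N = S = Nd = Sd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue
        for c in (c1, c2):
            syn = 0.0
            for pos in range(3):
                alts = [c[:pos] + n + c[pos + 1:] for n in "ACGT"
                        if n != c[pos]]
                alts = [a for a in alts if a not in _STOPS]
                if alts:
                    syn += sum(_aa(a) == _aa(c) for a in alts) / len(alts)
            S += syn / 2.0
            N += (3.0 - syn) / 2.0
        diff = [k for k in range(3) if c1[k] != c2[k]]
        if not diff:
            continue
        results = []
        for order in permutations(diff):
            cur, syn, nonsyn, blocked = c1, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in _STOPS:
                    blocked = True
                elif _aa(cur) == _aa(nxt) and cur not in _STOPS:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            results.append((blocked, syn, nonsyn))
        usable = [(s, n) for b, s, n in results if not b]
        if not usable:  # all pathways blocked by a stop: use them anyway
            usable = [(s, n) for b, s, n in results]
        Sd += sum(s for s, _ in usable) / len(usable)
        Nd += sum(n for _, n in usable) / len(usable)
    return N, S, Nd, Sd


# ---------------------------------------------------------------------------
# Small-tree codon likelihood by state enumeration
# ---------------------------------------------------------------------------

def three_taxon_loglikelihood(aln_states, branch_lengths, Q, pi):
    """lnL of a rooted 3-taxon tree ((A:ta,B:tb):tab,C:tc) by summing over
    both internal node states, with expm-based transition matrices.

    ``aln_states``: (3, n_sites) codon indices for A, B, C; ``branch_lengths``
    = (ta, tb, tab, tc); ``Q`` a single rate matrix shared by all branches.
    """
    from scipy.linalg import expm
    ta, tb, tab, tc = branch_lengths
    PA, PB, PAB, PC = (expm(Q * t) for t in (ta, tb, tab, tc))
    A, B, C = aln_states
    lnl = 0.0
    n_states = Q.shape[0]
    for site in range(aln_states.shape[1]):
        total = 0.0
        for root in range(n_states):
            pc = PC[root, C[site]]
            inner = 0.0
            for mid in range(n_states):
                inner += PAB[root, mid] * PA[mid, A[site]] * PB[mid, B[site]]
            total += pi[root] * inner * pc
        lnl += np.log(total)
    return lnl
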