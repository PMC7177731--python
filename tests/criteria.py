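"""Acceptance-level computations shared by the acceptance test suite and
scripts/acceptance.py. Every function runs the package end to end on
simulated or packaged inputs and returns measured quantities; the callers
decide what to assert or report.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

from genefamkit import (branchsite as bs, ddpcr, homology as h, phylo,
                        pipeline as pl, reconcile as rc, simulate as sg)
from tests import oracles


# ---------------------------------------------------------------------------
# Printed-table recomputations
# ---------------------------------------------------------------------------

def printed_table_values() -> dict:
    """The eight desk-verifiable quantities from the packaged tables."""
    regions = pl.load_region_table()
    expr = pl.load_expression_table()
    gs = regions.family == "GS"
    pepc = regions.family == "PEPC"
    out = {}
    out["gs_region_gc_mean_percent"], _ = pl.table_summary(
        regions, "column_mean", "gc_percent", subset=gs)
    out["gs_region_repeat_max_percent"], out["gs_region_repeat_max_id"] = \
        pl.table_summary(regions, "max", "repeat_percent", subset=gs,
                         id_column="gene_variant")
    out["pepc_region_repeat_min_percent"], out["pepc_region_repeat_min_id"] = \
        pl.table_summary(regions, "min", "repeat_percent", subset=pepc,
                         id_column="gene_variant")
    out["pepc_region_repeat_max_percent"], out["pepc_region_repeat_max_id"] = \
        pl.table_summary(regions, "max", "repeat_percent", subset=pepc,
                         id_column="gene_variant")
    genes_only = expr[expr.family != "reference"]
    out["leaf_expression_max_mean"], out["leaf_expression_max_gene"] = \
        pl.table_summary(genes_only, "max", "mean_expression",
                         id_column="gene")
    out["gs1_expression_max_mean"], out["gs1_expression_max_gene"] = \
        pl.table_summary(expr, "max", "mean_expression",
                         subset=expr.family == "GS1", id_column="gene")
    from genefamkit.genomics import GeneFeature, gene_structure_summary
    table, _ = gene_structure_summary(
        [GeneFeature("GS2a1", exons=[(1, 1299)], cds_length=1299),
         GeneFeature("PEPC5", exons=[(1, 3135)], cds_length=3135)])
    by_gene = table.set_index("gene")["protein_length_aa"]
    out["gs2_protein_length_aa"] = int(by_gene["GS2a1"])
    out["pepc5_protein_length_aa"] = int(by_gene["PEPC5"])
    return out


# ---------------------------------------------------------------------------
# Reconciliation oracle equivalence
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _species_tree(nwk: str):
    t = phylo.read_newick(nwk, rooted=True)
    sg.ensure_node_labels(t)
    return t


def reconciliation_oracle_agreement(seed: int = 0) -> dict:
    """LCA cost vs brute-force minimum over exhaustive small gene trees.

    Exhaustive: every rooted binary gene-tree shape with 2-4 leaves over
    every species assignment on a 3-taxon species tree (~1.3k cases), plus
    200 seeded random 5-6 leaf gene trees over a 4-taxon species tree.
    """
    rng = np.random.default_rng(seed)
    cases = agreements = 0

    def run_case(species_nwk, assignment, shape):
        nonlocal cases, agreements
        labels = [f"{sp}_{i}" for i, sp in enumerate(assignment)]
        it = iter(labels)

        def fill(t):
            if isinstance(t, str):
                return next(it)
            return (fill(t[0]), fill(t[1]))

        nwk = oracles.topology_to_newick(fill(shape)) + ";"
        g = phylo.read_newick(nwk, rooted=True)
        s = _species_tree(species_nwk)
        leaf_map = {lab: lab.split("_")[0] for lab in labels}
        res = rc.lca_reconcile(g, s, leaf_map)
        cost, _, _ = oracles.brute_force_min_dl(g, s, leaf_map)
        cases += 1
        agreements += res.cost == cost

    sp3 = "((A:1,B:1):1,C:2);"
    species3 = ["A", "B", "C"]
    for n in (2, 3, 4):
        shapes = oracles.enumerate_rooted_topologies([f"x{i}" for i in range(n)])
        for shape in shapes:
            for assignment in product(species3, repeat=n):
                run_case(sp3, assignment, shape)

    sp4 = "((A:1,B:1):1,(C:1,D:1):1);"
    species4 = ["A", "B", "C", "D"]
    for _ in range(200):
        n = int(rng.integers(5, 7))
        shapes = oracles.enumerate_rooted_topologies([f"x{i}" for i in range(n)])
        shape = shapes[int(rng.integers(len(shapes)))]
        assignment = [species4[i] for i in rng.integers(0, 4, size=n)]
        run_case(sp4, assignment, shape)

    return {"cases": cases, "agreement_rate": agreements / cases}


# ---------------------------------------------------------------------------
# NG86 oracle equivalence
# ---------------------------------------------------------------------------

def ng86_oracle_agreement(seed: int = 0, n_pairs: int = 500) -> dict:
    from genefamkit import codonmodel as cm
    from genefamkit.kaks import ng86_kaks
    rng = np.random.default_rng(seed)
    codons = list(cm.CODONS)
    agree = 0
    for _ in range(n_pairs):
        L = int(rng.integers(5, 25))
        a = "".join(rng.choice(codons, size=L))
        b = "".join(rng.choice(codons, size=L))
        r = ng86_kaks(a, b)
        N, S, Nd, Sd = oracles.ng86_counts_oracle(a, b)
        agree += (abs(r.N - N) < 1e-9 and abs(r.S - S) < 1e-9
                  and abs(r.Nd - Nd) < 1e-9 and abs(r.Sd - Sd) < 1e-9)
    return {"pairs": n_pairs, "agreement_rate": agree / n_pairs}


# ---------------------------------------------------------------------------
# Branch-site calibration
# ---------------------------------------------------------------------------

_SIX_TAXON = ("(((A:0.2,B:0.2):0.15,(C:0.2,D:0.2):0.15):0.1,"
              "(E:0.3,F:0.3):0.1);")


def _six_taxon_tree():
    t = phylo.read_newick(_SIX_TAXON, rooted=True)
    sg.ensure_node_labels(t)
    return t


def branch_site_type1_error(seed: int = 0, n_replicates: int = 200,
                            n_codons: int = 300, alpha: float = 0.05) -> dict:
    """Empirical rejection rate of the LRT on data simulated under the null
    (omega2 = 1) on a 6-taxon tree."""
    tree = _six_taxon_tree()
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        aln = sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=n_codons, omega0=0.2,
                                    omega2=1.0, p0=0.7, p1=0.2,
                                    seed=int(rng.integers(2 ** 31))))
        out = bs.branch_site_test(tree, aln, "N1", alpha=alpha,
                                  seed=int(rng.integers(2 ** 31)))
        rejections += out.significant
    return {"replicates": n_replicates, "alpha": alpha,
            "rejection_rate": rejections / n_replicates}


def branch_site_power(seed: int = 0, n_replicates: int = 100,
                      n_codons: int = 500, omega2: float = 8.0,
                      p2: float = 0.15, alpha: float = 0.05) -> dict:
    """Rejection rate and NEB site precision under episodic positive
    selection on the foreground branch (p2 of sites at omega2)."""
    tree = _six_taxon_tree()
    rng = np.random.default_rng(seed)
    p0 = (1.0 - p2) * 2.0 / 3.0
    p1 = (1.0 - p2) / 3.0
    rejections = 0
    neb_true = neb_total = 0
    for _ in range(n_replicates):
        aln = sg.simulate_codon_alignment(
            tree, sg.CodonSimParams(alignment_length=n_codons, omega0=0.2,
                                    omega2=omega2, p0=p0, p1=p1,
                                    foreground_branches={"N1"},
                                    seed=int(rng.integers(2 ** 31))))
        out = bs.branch_site_test(tree, aln, "N1", alpha=alpha,
                                  seed=int(rng.integers(2 ** 31)))
        rejections += out.significant
        if out.significant and out.neb_sites:
            truth = np.isin(aln.meta["site_classes"], ["2a", "2b"])
            hits = [i for i, _ in out.neb_sites]
            neb_true += int(truth[hits].sum())
            neb_total += len(hits)
    return {"replicates": n_replicates, "rejection_rate":
            rejections / n_replicates,
            "neb_precision": (neb_true / neb_total) if neb_total else None,
            "neb_sites_reported": neb_total}


# ---------------------------------------------------------------------------
# Clustering recovery
# ---------------------------------------------------------------------------

def clustering_recovery(seed: int = 0, n_graphs: int = 50) -> dict:
    """MCL + silhouette selection on planted 3-block graphs with jittered
    weights; counts exact partition recoveries."""
    recovered = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        import networkx as nx
        G = nx.Graph()
        G.graph["cap"] = 200.0
        sizes = rng.integers(5, 9, size=3)
        names = [f"b{k}_{i}" for k in range(3) for i in range(sizes[k])]
        block = {v: v.split("_")[0] for v in names}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                w = 200.0 if block[a] == block[b] else 5.0
                G.add_edge(a, b, weight=max(0.5, w + rng.normal(0, 10.0)))
        best, _ = h.select_inflation(G)
        truth = {}
        for v in names:
            truth.setdefault(block[v], set()).add(v)
        got = {frozenset(v) for v in best.clusters().values()}
        recovered += got == {frozenset(v) for v in truth.values()}
    return {"graphs": n_graphs, "recovery_rate": recovered / n_graphs}


# ---------------------------------------------------------------------------
# Duplication-timing recovery
# ---------------------------------------------------------------------------

def duplication_timing_recovery(seed: int = 0, n_families: int = 200) -> dict:
    """Reconciled duplication branches vs the simulation event log on
    families with a retention-0.8 WGD and low background rates."""
    spec = sg.SpeciesTreeSpec(
        "((A:1,B:1):0.5,(C:1,D:0.8):0.7);",
        [sg.WGDEvent("N1", 0.5, 0.8, 2)])
    sp_tree = spec.tree()
    rng = np.random.default_rng(seed)
    total = correct = 0
    for _ in range(n_families):
        tree, log = sg.simulate_gene_tree(
            spec, sg.FamilySimParams(birth_rate=0.05, death_rate=0.02,
                                     tandem_fraction=0.2,
                                     seed=int(rng.integers(2 ** 31))))
        if sg.count_extant_genes(tree) < 2:
            continue
        res = rc.lca_reconcile(tree, sp_tree, sg.leaf_map_from_labels(tree))
        inferred = {row["node"]: row["species_branch"]
                    for row in rc.classify_duplication_timing(res, sp_tree)}
        for rec in log.surviving_duplications():
            total += 1
            correct += inferred.get(rec.node_id) == rec.species_branch
    return {"families": n_families, "duplications": total,
            "correct_branch_rate": correct / total if total else None}


# ---------------------------------------------------------------------------
# ddPCR round trip
# ---------------------------------------------------------------------------

def ddpcr_ci_coverage(seed: int = 0, n_assays: int = 100,
                      lam_true: float = 1.2, n_droplets: int = 17_000) -> dict:
    rng = np.random.default_rng(seed)
    inside = 0
    for _ in range(n_assays):
        a = sg.simulate_droplets(n_droplets, lam_true,
                                 seed=int(rng.integers(2 ** 31)))
        _, (lo, hi) = ddpcr.poisson_concentration(a)
        inside += lo <= lam_true <= hi
    return {"assays": n_assays, "coverage_rate": inside / n_assays}


# ---------------------------------------------------------------------------
# NJ additivity
# ---------------------------------------------------------------------------

def nj_additivity_recovery(seed: int = 0, n_trees: int = 50) -> dict:
    import random
    from tests.test_phylo import additive_matrix_from_tree, random_tree
    pyrng = random.Random(seed)
    exact = 0
    for _ in range(n_trees):
        tree = random_tree(pyrng.randint(5, 12), pyrng)
        ids, D = additive_matrix_from_tree(tree)
        exact += phylo.rf_distance(phylo.nj_tree(ids, D), tree) == 0
    return {"trees": n_trees, "exact_recovery_rate": exact / n_trees}
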