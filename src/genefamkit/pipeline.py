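"""End-to-end orchestration and packaged reference tables.

``run_family_analysis`` drives the full chain on simulated gene families:
simulate -> cluster -> alignment QC -> NJ gene trees -> duplication/loss
reconciliation -> selection scan, producing a deterministic, JSON-ready
summary. The packaged CSV fixtures transcribe published region, expression
and primer tables for desk-scale verification queries (:func:`table_summary`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignqc, homology, kaks, phylo, reconcile, simulate
from .homology import Clustering, HitRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Packaged printed tables
# ---------------------------------------------------------------------------

def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("genefamkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_region_table() -> pd.DataFrame:
    """Published region characterization (18 rows: 9 GS + 9 PEPC)."""
    df = _load_csv("table1_regions.csv")
    assert len(df) == 18
    return df


def load_expression_table() -> pd.DataFrame:
    """Published leaf expression of GS/PEPC paralogs (20 rows)."""
    df = _load_csv("table4_expression.csv")
    assert len(df) == 20
    return df


def load_primer_table() -> pd.DataFrame:
    """Published probe primer pairs (2 rows)."""
    df = _load_csv("table5_primers.csv")
    assert len(df) == 2
    return df


def table_summary(table: pd.DataFrame, query: str, column: str,
                  subset: pd.Series | None = None, id_column: str | None = None,
                  ndigits: int = 2):
    """Summary queries over a printed table.

    ``query`` is one of ``column_mean`` (mean of ``column``, rounded),
    ``max`` / ``min`` (extreme of ``column`` with the row id from
    ``id_column``). ``subset`` is an optional boolean mask.
    """
    df = table if subset is None else table[subset]
    values = pd.to_numeric(df[column], errors="coerce")
    if query == "column_mean":
        return round(float(values.mean()), ndigits), None
    if query in ("max", "min"):
        idx = values.idxmax() if query == "max" else values.idxmin()
        row_id = df.loc[idx, id_column] if id_column else idx
        return float(values.loc[idx]), row_id
    raise ValueError(f"unknown query {query!r}")


def keep_clusters_containing(clustering: Clustering, seed_ids) -> Clustering:
    """Retain only clusters that contain at least one seed id (supervised
    post-filter: keep the clusters holding the golden-standard hits)."""
    seeds = set(seed_ids)
    if not seeds:
        raise ValueError("seed_ids must be non-empty")
    keep = {c for node, c in clustering.labels.items() if node in seeds}
    if not keep:
        raise ValueError("no cluster contains any seed id")
    labels = {n: c for n, c in clustering.labels.items() if c in keep}
    return Clustering(labels=labels, inflation=clustering.inflation,
                      silhouette=clustering.silhouette,
                      meta={**clustering.meta, "kept_clusters": sorted(keep)})


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a simulated end-to-end run."""

    species_newick: str
    wgd_events: list = field(default_factory=list)
    n_families: int = 4
    birth_rate: float = 0.05
    death_rate: float = 0.02
    tandem_fraction: float = 0.1
    codon_length: int = 300
    subst_per_time: float = 0.2  # converts tree time units to subs/codon
    seed: int = 0
    inflations: tuple = (1.2, 1.4, 2.0, 4.0, 6.0)
    occupancy: float = 0.01
    stages: tuple = ("simulate", "cluster", "qc", "trees", "reconcile",
                     "selection")
    out_dir: str | None = None


def _synthetic_hits(alignments: dict) -> list[HitRecord]:
    """Homology hits derived from simulated families: within-family pairs get
    an e-value exponent proportional to sequence identity (a stand-in for a
    search engine on data where true families are known)."""
    hits = []
    for fam, aln in alignments.items():
        chars = aln.char_matrix()
        for i in range(aln.n_sequences):
            for j in range(aln.n_sequences):
                if i == j:
                    continue
                ident = float((chars[i] == chars[j]).mean())
                exponent = max(5.0, 300.0 * max(0.0, ident - 0.30))
                hits.append(HitRecord(aln.ids[i], aln.ids[j],
                                      10.0 ** -exponent, coverage=1.0))
    return hits


def run_family_analysis(config: RunConfig) -> dict:
    """Execute the configured stages; returns a JSON-serialisable summary.

    Fully deterministic for a fixed ``config.seed``; every stage validates
    its inputs and a failure halts the run naming the stage.
    """
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    species = simulate.SpeciesTreeSpec(config.species_newick, config.wgd_events)
    families, alignments, logs, leaf_maps = {}, {}, {}, {}

    stage = "simulate"
    try:
        for f in range(config.n_families):
            fam = f"fam{f}"
            params = simulate.FamilySimParams(
                birth_rate=config.birth_rate, death_rate=config.death_rate,
                tandem_fraction=config.tandem_fraction,
                seed=int(rng.integers(2 ** 31)))
            tree, log = simulate.simulate_gene_tree(species, params)
            n_leaves = simulate.count_extant_genes(tree)
            if n_leaves < 3:
                continue  # too small for tree building; skip
            for node in tree.preorder_node_iter():
                if node.edge.length:
                    node.edge.length *= config.subst_per_time
            aln = simulate.simulate_codon_alignment(
                tree, simulate.CodonSimParams(
                    alignment_length=config.codon_length,
                    seed=int(rng.integers(2 ** 31))))
            for node in tree.preorder_node_iter():  # back to time units
                if node.edge.length:
                    node.edge.length /= config.subst_per_time
            # family-qualified gene ids keep leaves unique across families
            mapping = {old: f"{fam}.{old}" for old in aln.ids}
            leaf_maps[fam] = {mapping[g]: sp for g, sp
                              in simulate.leaf_map_from_labels(tree).items()}
            for leaf in tree.leaf_node_iter():
                leaf.taxon.label = mapping[leaf.taxon.label]
            aln = type(aln)([mapping[i] for i in aln.ids], aln.rows, aln.meta)
            families[fam], alignments[fam], logs[fam] = tree, aln, log
        summary["families"] = {
            fam: {"n_genes": alignments[fam].n_sequences} for fam in families}
        logger.info("stage=simulate families=%d elapsed=%.2fs",
                    len(families), time.time() - t0)

        if "cluster" in config.stages:
            stage = "cluster"
            hits = homology.filter_hits(_synthetic_hits(alignments),
                                        max_e=1e-20, min_cov=0.40)
            graph = homology.build_similarity_graph(hits)
            best, table = homology.select_inflation(graph, config.inflations)
            truth = {sid: fam for fam, aln in alignments.items()
                     for sid in aln.ids}
            recovered = _partitions_agree(best.labels, truth)
            summary["clustering"] = {
                "inflation": best.inflation,
                "n_clusters": best.n_clusters,
                "silhouette": round(best.silhouette, 6),
                "matches_true_families": recovered,
                "table": [[row.inflation, row.n_clusters,
                           None if pd.isna(row.silhouette) else round(row.silhouette, 6)]
                          for row in table.itertuples()],
            }

        if "qc" in config.stages:
            stage = "qc"
            qc_info = {}
            for fam, aln in alignments.items():
                outliers = alignqc.flag_gap_outliers(aln) if aln.n_sequences >= 4 else []
                trimmed = alignqc.trim_by_occupancy(aln, config.occupancy)
                qc_info[fam] = {"outliers": outliers,
                                "columns_kept": trimmed.n_codons}
                alignments[fam] = trimmed
            summary["qc"] = qc_info

        trees = {}
        if "trees" in config.stages:
            stage = "trees"
            for fam, aln in alignments.items():
                ids, D, _ = phylo.pairwise_distance(aln)
                trees[fam] = phylo.nj_tree(ids, D)
            summary["trees"] = {fam: phylo.write_newick(t).strip()
                                for fam, t in trees.items()}

        if "reconcile" in config.stages:
            stage = "reconcile"
            sp_tree = species.tree()
            rec_info = {}
            for fam, tree in families.items():
                res = reconcile.lca_reconcile(tree, sp_tree, leaf_maps[fam])
                timing = reconcile.classify_duplication_timing(res, sp_tree)
                rec_info[fam] = {
                    "D": res.duplications, "L": res.losses,
                    "cost": res.cost,
                    "true_duplications": len(logs[fam].surviving_duplications()),
                    "timing": {row["node"]: row["label"] for row in timing},
                }
            summary["reconciliation"] = rec_info

        if "selection" in config.stages:
            stage = "selection"
            kaks_rows = []
            for fam, tree in families.items():
                pairs = _sister_pairs(tree)
                if not pairs:
                    continue
                table = kaks.kaks_pair_table(alignments[fam], pairs)
                for row in table.itertuples():
                    kaks_rows.append({
                        "family": fam, "pair": [row.seq1, row.seq2],
                        "ka": _round(row.ka), "ks": _round(row.ks),
                        "ratio": _round(row.ratio),
                        "classification": row.classification})
            summary["kaks"] = kaks_rows
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["elapsed_s"] = round(time.time() - t0, 2)
    payload = json.dumps({k: v for k, v in summary.items() if k != "elapsed_s"},
                         sort_keys=True)
    summary["digest"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
    return summary


def _round(x, nd=4):
    import math
    return None if x is None or (isinstance(x, float) and math.isnan(x)) \
        else round(float(x), nd)


def _sister_pairs(tree) -> list[tuple[str, str]]:
    """Leaf pairs that are sisters (cherries) in the gene tree."""
    pairs = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            pairs.append((kids[0].taxon.label, kids[1].taxon.label))
    return sorted(pairs)


def _partitions_agree(labels: dict, truth: dict) -> bool:
    """True if two labelings induce the same partition of the common keys."""
    keys = sorted(set(labels) & set(truth))
    by_a: dict = {}
    by_b: dict = {}
    for k in keys:
        by_a.setdefault(labels[k], set()).add(k)
        by_b.setdefault(truth[k], set()).add(k)
    return sorted(map(sorted, by_a.values())) == sorted(map(sorted, by_b.values()))
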