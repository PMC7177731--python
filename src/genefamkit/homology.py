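"""Gene-family construction from all-vs-all homology hits.

Hits (BLAST tabular style) are filtered on e-value and reference coverage,
turned into an undirected similarity graph weighted by -log10(e-value)
(capped), clustered with an internally implemented Markov clustering (MCL)
procedure, and the inflation parameter is chosen by averaged silhouette
width. Sequence search itself is out of scope: this module starts from a
hit table produced by any search engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

DEFAULT_EVALUE_CAP = 200.0  # -log10 weight assigned to e-values of 0


@dataclass
class HitRecord:
    """One pairwise homology hit."""

    query: str
    subject: str
    evalue: float
    coverage: float  # alignment coverage of the designated reference sequence
    bitscore: float | None = None

    def __post_init__(self):
        if not self.query or not self.subject:
            raise ValueError("hit ids must be non-empty")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class Clustering:
    """A hard partition of graph nodes, with the inflation that produced it
    and (when defined) the averaged silhouette width."""

    labels: dict            # node id -> cluster index
    inflation: float
    silhouette: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def clusters(self) -> dict:
        out: dict[int, list] = {}
        for node, c in self.labels.items():
            out.setdefault(c, []).append(node)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()),
            columns=["node", "cluster"]).assign(inflation=self.inflation)


# ---------------------------------------------------------------------------
# Hit parsing and filtering
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path,
                   reference_lengths: Mapping[str, int]) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular (outfmt 6) file.

    Coverage is computed as alignment length / reference length, where the
    reference is the subject if it has a designated length, otherwise the
    query (mirroring coverage "of at least one of the reference homologs").
    Malformed rows raise with the 1-based line number.
    """
    hits = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {ln}: expected 12 columns, got {len(parts)}")
            try:
                q, s = parts[0], parts[1]
                aln_len = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from None
            ref_len = reference_lengths.get(s) or reference_lengths.get(q)
            if ref_len is None:
                raise ValueError(
                    f"line {ln}: neither {q!r} nor {s!r} has a reference length")
            hits.append(HitRecord(q, s, evalue, min(1.0, aln_len / ref_len),
                                  bitscore))
    return hits


def filter_hits(hits: Iterable[HitRecord], max_e: float = 1e-20,
                min_cov: float = 0.40) -> list[HitRecord]:
    """Retain hits with e-value <= max_e and reference coverage >= min_cov.

    Order-stable and idempotent.
    """
    if max_e < 0 or not 0 <= min_cov <= 1:
        raise ValueError("thresholds out of range")
    return [h for h in hits if h.evalue <= max_e and h.coverage >= min_cov]


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def build_similarity_graph(hits: Iterable[HitRecord],
                           cap: float = DEFAULT_EVALUE_CAP) -> nx.Graph:
    """Undirected graph with w(i, j) = min(-log10 e-value, cap).

    Reciprocal hits are merged by taking the maximum weight; self-hits are
    dropped. Every id seen in a hit becomes a node (so singletons survive).
    """
    G = nx.Graph()
    for h in hits:
        G.add_node(h.query)
        G.add_node(h.subject)
        if h.query == h.subject:
            continue
        w = cap if h.evalue == 0 else min(-np.log10(h.evalue), cap)
        w = max(w, 0.0)
        prev = G.get_edge_data(h.query, h.subject)
        if prev is None or prev["weight"] < w:
            G.add_edge(h.query, h.subject, weight=w)
    G.graph["cap"] = cap
    return G


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(graph: nx.Graph, inflation: float, floor: float = 1e-6,
                max_iter: int = 200, tol: float = 1e-8) -> Clustering:
    """Markov clustering of a weighted graph.

    The column-stochastic transition matrix (with self-loops weighted by each
    node's maximum incident edge weight, so attractors are stable) is
    alternately expanded (matrix squared) and inflated (elementwise power
    ``inflation``, then column renormalisation); entries below ``floor`` are
    pruned. Iteration stops when the largest column change falls below
    ``tol``; clusters are read from attractor connectivity. Deterministic
    for a fixed node ordering (nodes are sorted internally).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = M[index[v], index[u]] = w
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0  # isolated nodes keep a unit self-loop
    np.fill_diagonal(M, loops)

    M /= M.sum(axis=0, keepdims=True)
    for iteration in range(max_iter):
        M2 = M @ M
        M2 **= inflation
        M2[M2 < floor] = 0.0
        colsum = M2.sum(axis=0)
        dead = colsum == 0  # fully pruned column: park mass on the node itself
        if dead.any():
            M2[dead, dead] = 1.0
            colsum[dead] = 1.0
        M2 /= colsum[None, :]
        delta = np.abs(M2 - M).max()
        M = M2
        if delta < tol:
            break
    else:
        raise RuntimeError(f"MCL did not converge in {max_iter} iterations "
                           f"(residual {delta:.3g})")

    # attractors: nodes with mass on their own column diagonal
    attractors = np.flatnonzero(np.diag(M) > floor)
    overlap = nx.Graph()
    overlap.add_nodes_from(range(n))
    for a in attractors:
        members = np.flatnonzero(M[a] > floor)
        for m in members:
            overlap.add_edge(a, m)
    labels = {}
    for cluster_idx, comp in enumerate(
            sorted(nx.connected_components(overlap), key=min)):
        for i in comp:
            labels[nodes[i]] = cluster_idx
    return Clustering(labels=labels, inflation=inflation,
                      meta={"iterations": iteration + 1})


# ---------------------------------------------------------------------------
# Inflation selection by silhouette
# ---------------------------------------------------------------------------

def graph_distance_matrix(graph: nx.Graph, cap: float | None = None):
    """Bounded similarity-to-distance transform d = 1 - w / cap
    (non-adjacent pairs get d = 1, the diagonal 0)."""
    cap = cap if cap is not None else graph.graph.get("cap", DEFAULT_EVALUE_CAP)
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    D = np.ones((len(nodes), len(nodes)))
    np.fill_diagonal(D, 0.0)
    for u, v, data in graph.edges(data=True):
        d = max(0.0, 1.0 - float(data.get("weight", 0.0)) / cap)
        D[index[u], index[v]] = D[index[v], index[u]] = d
    return nodes, D


def average_silhouette(graph: nx.Graph, clustering: Clustering,
                       cap: float | None = None) -> float:
    """Averaged silhouette width of a clustering on the graph distances."""
    nodes, D = graph_distance_matrix(graph, cap)
    labels = np.array([clustering.labels[v] for v in nodes])
    k = len(set(labels))
    if k < 2 or k >= len(nodes):
        raise ValueError("silhouette undefined: need 2 <= clusters < nodes, "
                         f"got {k} clusters on {len(nodes)} nodes")
    return float(np.mean(silhouette_samples(D, labels, metric="precomputed")))


def select_inflation(graph: nx.Graph,
                     candidates: Sequence[float] = (1.2, 1.4, 2.0, 4.0, 6.0),
                     cap: float | None = None):
    """Cluster at every candidate inflation and keep the best silhouette.

    Returns ``(best_clustering, table)`` where the table lists
    (inflation, n_clusters, silhouette) for every candidate. Ties on the
    silhouette (within 1e-12) are broken toward the smallest inflation; if a
    candidate yields a single cluster its silhouette is undefined and it can
    only be selected if every candidate does (which raises).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate inflations")
    rows, results = [], []
    for I in candidates:
        clustering = mcl_cluster(graph, I)
        s = None
        if 2 <= clustering.n_clusters < graph.number_of_nodes():
            s = average_silhouette(graph, clustering, cap)
        clustering.silhouette = s
        results.append(clustering)
        rows.append({"inflation": I, "n_clusters": clustering.n_clusters,
                     "silhouette": s})
    table = pd.DataFrame(rows)
    scored = [r for r in results if r.silhouette is not None]
    if not scored:
        raise ValueError("silhouette undefined: every candidate inflation "
                         "produced a single cluster")
    best = scored[0]
    for r in scored[1:]:
        if r.silhouette > best.silhouette + 1e-12:
            best = r
    return best, table


# ---------------------------------------------------------------------------
# Single-copy locus selection
# ---------------------------------------------------------------------------

def select_single_copy_loci(ortholog_table: Mapping[str, Mapping[str, int]],
                            n_genomes: int,
                            min_fraction: float = 0.95) -> list[str]:
    """Loci represented as exactly single-copy in more than ``min_fraction``
    of the genomes (absent genomes count as zero copies)."""
    if not ortholog_table:
        warnings.warn("empty ortholog table")
        return []
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    out = []
    for locus, counts in ortholog_table.items():
        single = sum(1 for c in counts.values() if c == 1)
        if single / n_genomes > min_fraction:
            out.append(locus)
    return out
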