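"""Ground-truth simulators for gene-family evolution.

Three generators make every downstream stage testable without external data:

* :func:`simulate_gene_tree` — a birth-death process of gene duplication and
  loss run along a rooted species tree (Gillespie sampling per lineage), with
  optional whole-genome-duplication (WGD) events that instantaneously copy
  every lineage alive at the event point (each copy retained independently
  with a stated probability; multiplicity 2 = duplication, 3 = triplication)
  and a configurable fraction of single-gene births labelled as tandem.
  The realised event history is returned as an :class:`EventLog`.

* :func:`simulate_codon_alignment` — codon sequences evolved along a gene
  tree under the GY94 model with branch-site class structure (classes 0, 1,
  2a, 2b; a designated foreground branch set on which the positive-selection
  class applies), sharing the rate-matrix engine with the inference code.

* :func:`simulate_droplets` — droplet digital PCR counts with Poisson
  template occupancy (a droplet is positive with probability 1 - e^-lambda).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import codonmodel as cm
from .alignments import CodonAlignment
from .ddpcr import DropletAssay

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class WGDEvent:
    """A whole-genome multiplication on one species-tree branch.

    ``branch`` names the head node of the branch (leaf label, or internal
    node label assigned by :func:`ensure_node_labels`); ``time_fraction`` is
    the position along the branch (0 = top, toward the root); ``retention``
    is the independent survival probability of each of the ``multiplicity``
    copies of every lineage alive at the event.
    """

    branch: str
    time_fraction: float
    retention: float
    multiplicity: int = 2

    def __post_init__(self):
        if not 0 < self.time_fraction < 1:
            raise ValueError("time_fraction must be in (0, 1)")
        if not 0 <= self.retention <= 1:
            raise ValueError("retention must be in [0, 1]")
        if self.multiplicity not in (2, 3):
            raise ValueError("WGD multiplicity must be 2 or 3")


@dataclass
class SpeciesTreeSpec:
    """Rooted binary species tree (Newick, branch lengths in time units)
    plus any WGD events placed on its branches."""

    newick: str
    wgd_events: list[WGDEvent] = field(default_factory=list)

    def tree(self) -> dendropy.Tree:
        tree = dendropy.Tree.get(data=self.newick, schema="newick",
                                 preserve_underscores=True,
                                 rooting="force-rooted")
        ensure_node_labels(tree)
        for node in tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError("negative branch length in species tree")
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and len(node.child_nodes()) != 2:
                raise ValueError("species tree must be binary")
        branches = {_node_id(n) for n in tree.preorder_node_iter()}
        for ev in self.wgd_events:
            if ev.branch not in branches:
                raise ValueError(f"WGD references unknown branch {ev.branch!r}")
        return tree


@dataclass
class FamilySimParams:
    """Birth-death rates per lineage per unit time."""

    birth_rate: float = 0.0
    death_rate: float = 0.0
    tandem_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.tandem_fraction <= 1:
            raise ValueError("tandem_fraction must be in [0, 1]")


@dataclass
class CodonSimParams:
    """Branch-site codon model parameters for the sequence simulator.

    Site-class proportions (p0, p1, p2) with omega values (omega0 in (0, 1],
    omega1 = 1 fixed, omega2 >= 1). Class-2 sites take omega2 on foreground
    branches; on background branches each class-2 site follows omega0 or
    omega1 with probability p0/(p0+p1) and p1/(p0+p1) (the 2a/2b split of
    the standard branch-site model A).
    """

    alignment_length: int = 300
    kappa: float = 2.0
    omega0: float = 0.2
    omega2: float = 1.0
    p0: float = 0.7
    p1: float = 0.2
    codon_freqs: np.ndarray | None = None
    foreground_branches: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0 < self.omega0 <= 1:
            raise ValueError("omega0 must be in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-9:
            raise ValueError("need p0, p1 >= 0 with p0 + p1 <= 1")
        if self.codon_freqs is None:
            self.codon_freqs = cm.uniform_codon_freqs()
        else:
            self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
            if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
                raise ValueError("codon_freqs must sum to 1")
        self.foreground_branches = frozenset(self.foreground_branches)

    @property
    def p2(self) -> float:
        return max(0.0, 1.0 - self.p0 - self.p1)


# ---------------------------------------------------------------------------
# Event log
# ---------------------------------------------------------------------------

EVENT_TYPES = ("speciation", "duplication", "tandem_duplication",
               "wgd_retention", "loss")


@dataclass
class EventRecord:
    event: str
    node_id: str | None  # gene-tree node label; None if the node did not survive
    species_branch: str
    time: float


class EventLog:
    """Realised event history of one simulated gene family.

    Records cover *all* events of the full (unpruned) lineage history; events
    whose gene-tree node was removed when extinct subtrees were pruned carry
    ``node_id = None``. Every internal node of the returned gene tree appears
    exactly once with its label.
    """

    def __init__(self, records: list[EventRecord] | None = None):
        self.records: list[EventRecord] = records or []

    def add(self, event: str, node_id: str | None, species_branch: str,
            time: float) -> None:
        if event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {event!r}")
        self.records.append(EventRecord(event, node_id, species_branch, time))

    def count(self, event: str) -> int:
        return sum(1 for r in self.records if r.event == event)

    @property
    def n_losses(self) -> int:
        return self.count("loss")

    def surviving(self, *events: str) -> list[EventRecord]:
        """Records of the given types whose node survives in the gene tree."""
        return [r for r in self.records
                if r.event in events and r.node_id is not None]

    def surviving_duplications(self) -> list[EventRecord]:
        return self.surviving("duplication", "tandem_duplication", "wgd_retention")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.event, r.node_id if r.node_id is not None else "",
              r.species_branch, r.time) for r in self.records],
            columns=["event", "node_id", "species_branch", "time"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Species-tree helpers
# ---------------------------------------------------------------------------

def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic labels N0, N1, ... (preorder) to unlabelled
    internal nodes so branches can be referenced by their head node."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"N{i}"
        i += 1
    return tree


def _node_id(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


# ---------------------------------------------------------------------------
# Gene-tree simulation
# ---------------------------------------------------------------------------


class _Lineage:
    """Node of the full (unpruned) gene lineage history."""

    __slots__ = ("event", "time", "species_branch", "children", "leaf_species")

    def __init__(self, event, time, species_branch, children=None,
                 leaf_species=None):
        self.event = event          # one of EVENT_TYPES, or "extant"/"extinct"
        self.time = time
        self.species_branch = species_branch
        self.children = children or []
        self.leaf_species = leaf_species


def simulate_gene_tree(species: SpeciesTreeSpec, params: FamilySimParams):
    """Run the duplication/loss birth-death process along the species tree.

    Returns ``(gene_tree, event_log)``. The gene tree is rooted and binary
    with leaves named ``<species>_g<k>``; a family with zero survivors is
    returned as an empty tree together with its loss-only log.
    """
    sp_tree = species.tree()
    rng = np.random.default_rng(params.seed)
    log = EventLog()
    lam, mu = params.birth_rate, params.death_rate
    total = lam + mu

    wgd_by_branch: dict[str, list[WGDEvent]] = {}
    for ev in species.wgd_events:
        wgd_by_branch.setdefault(ev.branch, []).append(ev)
    for evs in wgd_by_branch.values():
        evs.sort(key=lambda e: e.time_fraction)

    depth: dict[dendropy.Node, float] = {}
    for node in sp_tree.preorder_node_iter():
        parent_depth = depth[node.parent_node] if node.parent_node else 0.0
        depth[node] = parent_depth + (node.edge.length or 0.0)

    def evolve_branch(sp_node: dendropy.Node, t_start: float) -> _Lineage:
        """Evolve one lineage from ``t_start`` down the branch above
        ``sp_node``; returns the lineage subtree rooted at the first event."""
        branch = _node_id(sp_node)
        t_top = depth[sp_node] - (sp_node.edge.length or 0.0)
        t_end = depth[sp_node]
        length = sp_node.edge.length or 0.0
        boundaries = [(t_top + ev.time_fraction * length, ev)
                      for ev in wgd_by_branch.get(branch, [])
                      if t_top + ev.time_fraction * length > t_start + 1e-15]
        return _evolve(sp_node, branch, t_start, t_end, boundaries)

    def _evolve(sp_node, branch, t, t_end, wgds) -> _Lineage:
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            t_next_wgd = wgds[0][0] if wgds else math.inf
            t_event = t + wait
            if t_event < min(t_next_wgd, t_end):
                if rng.random() < (lam / total if total else 0.0):
                    tandem = rng.random() < params.tandem_fraction
                    kind = "tandem_duplication" if tandem else "duplication"
                    left = _evolve(sp_node, branch, t_event, t_end, list(wgds))
                    right = _evolve(sp_node, branch, t_event, t_end, list(wgds))
                    return _Lineage(kind, t_event, branch, [left, right])
                log.add("loss", None, branch, t_event)
                return _Lineage("extinct", t_event, branch)
            if t_next_wgd < t_end:
                t_w, ev = wgds[0]
                rest = wgds[1:]
                kept = int(np.sum(rng.random(ev.multiplicity) < ev.retention))
                if kept == 0:
                    log.add("loss", None, branch, t_w)
                    return _Lineage("extinct", t_w, branch)
                subs = [_evolve(sp_node, branch, t_w, t_end, list(rest))
                        for _ in range(kept)]
                node = subs[0]
                for other in subs[1:]:  # chain retained copies as binary nodes
                    node = _Lineage("wgd_retention", t_w, branch, [node, other])
                return node
            # reached the bottom of the branch
            if sp_node.is_leaf():
                return _Lineage("extant", t_end, branch,
                                leaf_species=_node_id(sp_node))
            children = [evolve_branch(c, t_end) for c in sp_node.child_nodes()]
            return _Lineage("speciation", t_end, _node_id(sp_node), children)

    root_sp = sp_tree.seed_node
    root_sp.edge.length = root_sp.edge.length or 0.0
    history = evolve_branch(root_sp, 0.0 - root_sp.edge.length)

    # --- prune extinct subtrees, suppress unifurcations, build dendropy ----
    def survives(lin: _Lineage) -> bool:
        if lin.event == "extant":
            return True
        if lin.event == "extinct":
            return False
        return any(survives(c) for c in lin.children)

    tns = dendropy.TaxonNamespace()
    gene_tree = dendropy.Tree(taxon_namespace=tns)
    gene_tree.is_rooted = True
    leaf_counter: dict[str, int] = {}
    node_counter = [0]

    def build(lin: _Lineage, parent_time: float):
        """Return a dendropy node for the surviving part of ``lin``."""
        if lin.event == "extant":
            sp = lin.leaf_species
            leaf_counter[sp] = leaf_counter.get(sp, 0) + 1
            node = dendropy.Node()
            node.taxon = tns.require_taxon(label=f"{sp}_g{leaf_counter[sp]}")
            node.edge.length = lin.time - parent_time
            return node
        alive = [c for c in lin.children if survives(c)]
        if len(alive) == 0:
            return None
        if len(alive) == 1:  # suppressed: event did not leave a binary node
            if lin.event != "extant":
                log.add(lin.event, None, lin.species_branch, lin.time)
            return build(alive[0], parent_time)
        node = dendropy.Node()
        label = f"g{node_counter[0]}"
        node_counter[0] += 1
        node.label = label
        node.edge.length = lin.time - parent_time
        log.add(lin.event, label, lin.species_branch, lin.time)
        for c in alive:
            node.add_child(build(c, lin.time))
        return node

    if not survives(history):
        return dendropy.Tree(taxon_namespace=tns), log

    root_node = build(history, 0.0 - root_sp.edge.length)
    if root_node.is_leaf():
        gene_tree.seed_node.add_child(root_node)
    else:
        gene_tree.seed_node = root_node
    return gene_tree, log


def count_extant_genes(gene_tree: dendropy.Tree) -> int:
    """Number of surviving gene copies (taxon-bearing leaves); an extinct
    family's empty tree counts 0."""
    return sum(1 for lf in gene_tree.leaf_node_iter() if lf.taxon is not None)


def leaf_map_from_labels(gene_tree: dendropy.Tree) -> dict[str, str]:
    """Recover the gene-leaf -> species map from ``<species>_g<k>`` labels."""
    out = {}
    for leaf in gene_tree.leaf_node_iter():
        label = leaf.taxon.label
        out[label] = label.rsplit("_g", 1)[0]
    return out


# ---------------------------------------------------------------------------
# Codon-alignment simulation
# ---------------------------------------------------------------------------

def simulate_codon_alignment(gene_tree: dendropy.Tree,
                             params: CodonSimParams) -> CodonAlignment:
    """Evolve a gap-free codon alignment along ``gene_tree``.

    Branch lengths must be in expected substitutions per codon site (at the
    site-class mixture). Per-site true class labels ("0", "1", "2a", "2b")
    are stored in ``meta["site_classes"]``.
    """
    for node in gene_tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise ValueError("negative branch length in gene tree")
    rng = np.random.default_rng(params.seed)
    pi = params.codon_freqs
    L = params.alignment_length
    p0, p1, p2 = params.p0, params.p1, params.p2

    # site classes, with the 2a/2b background split
    u = rng.random(L)
    classes = np.where(u < p0, 0, np.where(u < p0 + p1, 1, 2))
    bg_is_0 = rng.random(L) < (p0 / (p0 + p1) if p0 + p1 > 0 else 0.5)
    labels = np.array(["0", "1", "2", "2"], dtype="U2")[classes]
    labels[(classes == 2) & bg_is_0] = "2a"
    labels[(classes == 2) & ~bg_is_0] = "2b"

    scale = cm.mixture_scale(
        params.kappa,
        [params.omega0, 1.0, params.omega0, 1.0],
        [p0, p1, p2 * (p0 / (p0 + p1) if p0 + p1 > 0 else 0.5),
         p2 * (p1 / (p0 + p1) if p0 + p1 > 0 else 0.5)],
        pi)
    matrices = {w: cm.ReversibleCodonMatrix(
        cm.rate_matrix(params.kappa, w, pi) / scale, pi)
        for w in {params.omega0, 1.0, params.omega2}}

    def branch_omegas(node) -> np.ndarray:
        fg = _node_id(node) in params.foreground_branches
        w = np.empty(L)
        w[labels == "0"] = params.omega0
        w[labels == "1"] = 1.0
        w[labels == "2a"] = params.omega2 if fg else params.omega0
        w[labels == "2b"] = params.omega2 if fg else 1.0
        return w

    states = {gene_tree.seed_node: rng.choice(cm.N_CODONS, size=L, p=pi)}
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node:
            continue
        parent_states = states[node.parent_node]
        t = node.edge.length or 0.0
        child = parent_states.copy()
        if t > 0:
            omegas = branch_omegas(node)
            for w in np.unique(omegas):
                P = matrices[float(w)].transition_matrix(t)
                cum = np.cumsum(P, axis=1)
                sel = omegas == w
                r = rng.random(int(sel.sum()))
                rows = cum[parent_states[sel]]
                child[sel] = (r[:, None] < rows).argmax(axis=1)
        states[node] = child

    ids, rows = [], []
    for leaf in gene_tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        rows.append(cm.states_to_seq(states[leaf]))
    aln = CodonAlignment(ids, rows)
    aln.meta["site_classes"] = labels
    return aln


# ---------------------------------------------------------------------------
# Droplet simulation
# ---------------------------------------------------------------------------

def simulate_droplets(n_droplets: int, mean_copies_per_droplet: float,
                      seed: int = 0, target: str = "target") -> DropletAssay:
    """Simulate a ddPCR assay: each droplet is positive with probability
    1 - exp(-lambda) (the Poisson zero class gives the negatives)."""
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    lam = mean_copies_per_droplet
    if lam < 0:
        raise ValueError("mean copies per droplet must be >= 0")
    rng = np.random.default_rng(seed)
    p_pos = 1.0 - math.exp(-lam)
    n_pos = int(rng.binomial(n_droplets, p_pos))
    return DropletAssay(n_total=n_droplets, n_negative=n_droplets - n_pos,
                        target=target)


# ---------------------------------------------------------------------------
# Gene-structure presets and bundle emission
# ---------------------------------------------------------------------------

#: modal exon counts of the families this simulator emulates: cytosolic GS
#: (12), plastid GS (13), plant-type PEPC (10), bacterial-type PEPC (20)
STRUCTURE_PRESETS = {
    "GS1": 12,
    "GS2": 13,
    "PEPC_plant": 10,
    "PEPC_bacterial": 20,
}


@dataclass
class StructureSpec:
    """Exon/intron layout for emitted gene models."""

    preset: str = "GS1"
    intron_length: int = 120

    def exon_count(self) -> int:
        if self.preset not in STRUCTURE_PRESETS:
            raise ValueError(f"unknown structure preset {self.preset!r}; "
                             f"choose from {sorted(STRUCTURE_PRESETS)}")
        return STRUCTURE_PRESETS[self.preset]


def emit_family_bundle(gene_tree: dendropy.Tree, alignment: CodonAlignment,
                       structures: StructureSpec, out_dir: str | Path,
                       event_log: EventLog | None = None,
                       family: str = "fam1", overwrite: bool = False) -> dict:
    """Write a simulated family to disk as standard text formats.

    Emits CDS and protein FASTA (60-column wrap), GFF3 gene structures with
    the preset exon count, the gene tree as Newick, the event log as TSV,
    and a true-cluster assignment table. Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("cds", "cds.fasta"), ("protein", "protein.fasta"),
        ("gff", "genes.gff3"), ("tree", "tree.nwk"),
        ("events", "events.tsv"), ("clusters", "clusters.tsv")]}
    clash = [p for p in paths.values() if p.exists()]
    if clash and not overwrite:
        raise FileExistsError(f"refusing to overwrite {clash[0]} "
                              "(pass overwrite=True)")

    if alignment.n_sequences == 0:
        warnings.warn("empty family: no FASTA records emitted")
    with open(paths["cds"], "w") as fh:
        for sid in alignment.ids:
            _write_fasta_record(fh, sid, alignment.ungapped(sid))
    with open(paths["protein"], "w") as fh:
        for sid in alignment.ids:
            cds = alignment.ungapped(sid)
            prot = "".join(cm.translate_codon(cds[i:i + 3])
                           for i in range(0, len(cds), 3))
            _write_fasta_record(fh, sid, prot)

    n_exons = structures.exon_count()
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for sid in alignment.ids:
            cds_len = len(alignment.ungapped(sid))
            _write_gene_gff3(fh, sid, cds_len, n_exons, structures.intron_length)

    from .phylo import write_newick
    if gene_tree.seed_node is not None and any(gene_tree.leaf_node_iter()):
        paths["tree"].write_text(write_newick(gene_tree))
    else:
        paths["tree"].write_text(";\n")
    (event_log or EventLog()).to_tsv(paths["events"])
    pd.DataFrame({"gene": alignment.ids, "cluster": family}).to_csv(
        paths["clusters"], sep="\t", index=False)
    return paths


def _write_fasta_record(fh, name: str, seq: str, width: int = 60) -> None:
    fh.write(f">{name}\n")
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")


def _write_gene_gff3(fh, gene_id: str, cds_len: int, n_exons: int,
                     intron_len: int) -> None:
    """One gene/mRNA/exon/CDS block; CDS split evenly over n_exons exons
    (1-based inclusive coordinates)."""
    n_exons = min(n_exons, max(1, cds_len // 3))  # never emit empty exons
    base = cds_len // n_exons
    sizes = [base + (1 if i < cds_len % n_exons else 0) for i in range(n_exons)]
    start = 1
    exons = []
    for s in sizes:
        exons.append((start, start + s - 1))
        start = exons[-1][1] + 1 + intron_len
    gene_end = exons[-1][1]
    seqid = f"{gene_id}_region"
    fh.write(f"{seqid}\tgenefamkit\tgene\t1\t{gene_end}\t.\t+\t.\tID={gene_id}\n")
    fh.write(f"{seqid}\tgenefamkit\tmRNA\t1\t{gene_end}\t.\t+\t.\t"
             f"ID={gene_id}.t1;Parent={gene_id}\n")
    for k, (a, b) in enumerate(exons, 1):
        fh.write(f"{seqid}\tgenefamkit\texon\t{a}\t{b}\t.\t+\t.\t"
                 f"ID={gene_id}.e{k};Parent={gene_id}.t1\n")
        fh.write(f"{seqid}\tgenefamkit\tCDS\t{a}\t{b}\t.\t+\t0\t"
                 f"ID={gene_id}.c{k};Parent={gene_id}.t1\n")


def read_family_bundle(out_dir: str | Path) -> dict:
    """Re-read an emitted bundle (round-trip helper)."""
    from Bio import SeqIO
    from .phylo import read_newick
    out = Path(out_dir)
    cds = {r.id: str(r.seq) for r in SeqIO.parse(str(out / "cds.fasta"), "fasta")}
    protein = {r.id: str(r.seq)
               for r in SeqIO.parse(str(out / "protein.fasta"), "fasta")}
    tree_text = (out / "tree.nwk").read_text().strip()
    tree = read_newick(tree_text, rooted=True) if tree_text not in (";", "") else None
    events = pd.read_csv(out / "events.tsv", sep="\t")
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    return {"cds": cds, "protein": protein, "tree": tree,
            "events": events, "clusters": clusters}
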