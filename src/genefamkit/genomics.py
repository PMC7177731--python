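"""Genome-region and gene-structure characterisation, plus microsynteny.

Regions (BAC inserts or assembly scaffolds, typically ~100 kbp) are
summarised by GC content, merged repeat-masked fraction, and gene count;
gene models by exon count and CDS/protein length (a complete CDS includes
its stop codon, the protein does not, so aa = bp/3 - 1). Microsynteny
between two regions is detected by chaining homology anchors into collinear
blocks with a weighted longest-increasing-subsequence dynamic programme;
repeat detection and gene prediction are upstream inputs, not computed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """A gene model: exon spans (1-based inclusive) and its CDS length."""

    gene_id: str
    exons: list = field(default_factory=list)   # [(start, end), ...]
    cds_length: int = 0
    strand: str = "+"
    complete: bool = True

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass
class RegionAnnotation:
    """One genome region: sequence, masked repeat intervals, gene features.

    Repeat intervals are 0-based half-open with a repeat class label,
    e.g. ``(100, 600, "Ty1/Copia")``.
    """

    region_id: str
    sequence: str | None = None
    length: int | None = None
    repeat_intervals: list = field(default_factory=list)
    genes: list = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.length is None:
                self.length = len(self.sequence)
        if self.length is None:
            raise ValueError("need sequence or explicit length")
        for start, end, _label in self.repeat_intervals:
            if not 0 <= start < end <= self.length:
                raise ValueError(f"interval ({start}, {end}) outside region")


def merge_intervals(intervals: Iterable[tuple]) -> list[tuple[int, int]]:
    """Merge possibly overlapping (start, end, ...) half-open intervals."""
    spans = sorted((i[0], i[1]) for i in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def region_stats(region: RegionAnnotation) -> dict:
    """GC %, merged repeat fraction/bp, repeat classes, and CDS count."""
    if region.sequence is not None:
        seq = region.sequence
        if not seq:
            raise ValueError("empty sequence")
        counts = Counter(seq)
        acgt = sum(counts[b] for b in "ACGT")
        if acgt == 0:
            raise ValueError("sequence has no unambiguous bases")
        gc = 100.0 * (counts["G"] + counts["C"]) / acgt
    else:
        gc = float("nan")
    repeat_bp = sum(e - s for s, e in merge_intervals(region.repeat_intervals))
    classes = sorted({label for _s, _e, label in region.repeat_intervals})
    return {
        "region": region.region_id,
        "gc_percent": gc,
        "repeat_percent": 100.0 * repeat_bp / region.length,
        "repeat_bp": repeat_bp,
        "repeat_classes": classes,
        "cds_count": sum(1 for g in region.genes if g.cds_length > 0),
        "length": region.length,
    }


def summarize_family_regions(stats: Sequence[dict], family: str) -> dict:
    """Family-level summary of region stats: mean GC (2 dp), repeat extremes
    with their region ids, mean CDS count."""
    if not stats:
        raise ValueError("no regions")
    lo = min(stats, key=lambda r: r["repeat_percent"])
    hi = max(stats, key=lambda r: r["repeat_percent"])
    return {
        "family": family,
        "n_regions": len(stats),
        "mean_gc_percent": round(sum(r["gc_percent"] for r in stats) / len(stats), 2),
        "min_repeat_percent": round(lo["repeat_percent"], 2),
        "min_repeat_region": lo["region"],
        "max_repeat_percent": round(hi["repeat_percent"], 2),
        "max_repeat_region": hi["region"],
        "mean_cds_count": round(sum(r["cds_count"] for r in stats) / len(stats), 2),
    }


def gene_structure_summary(genes: Sequence[GeneFeature]):
    """Per-gene (exon count, CDS bp, protein aa) table and the family's
    modal exon count (ties reported as a list)."""
    rows = []
    for g in genes:
        if g.complete:
            if g.cds_length % 3:
                raise ValueError(f"{g.gene_id}: complete CDS length "
                                 f"{g.cds_length} not divisible by 3")
            protein = g.cds_length // 3 - 1  # stop codon excluded
        else:
            protein = g.cds_length // 3
        rows.append({"gene": g.gene_id, "exon_count": g.exon_count,
                     "cds_length_bp": g.cds_length,
                     "protein_length_aa": protein,
                     "complete": g.complete})
    table = pd.DataFrame(rows)
    counts = Counter(table["exon_count"])
    top = max(counts.values())
    modes = sorted(k for k, v in counts.items() if v == top)
    return table, (modes[0] if len(modes) == 1 else modes)


# ---------------------------------------------------------------------------
# GFF3 / BED input
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> dict[str, list]:
    """BED (0-based half-open) -> {region: [(start, end, label), ...]}."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {ln}: BED needs >= 3 columns")
            label = parts[3] if len(parts) > 3 else "repeat"
            out.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), label))
    return out


def read_gff3_genes(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Parse gene/mRNA/exon/CDS features from GFF3 into GeneFeature lists
    keyed by sequence region (gffutils-backed)."""
    import gffutils
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    out: dict[str, list[GeneFeature]] = {}
    for gene in db.features_of_type("gene"):
        exons, cds_len = [], 0
        for child in db.children(gene, featuretype="exon"):
            exons.append((child.start, child.end))
        for child in db.children(gene, featuretype="CDS"):
            cds_len += child.end - child.start + 1
        for a, b in exons:
            if a < gene.start or b > gene.end:
                raise ValueError(f"{gene.id}: exon ({a}, {b}) outside gene span")
        out.setdefault(gene.seqid, []).append(
            GeneFeature(gene_id=gene.id, exons=sorted(exons),
                        cds_length=cds_len, strand=gene.strand or "+"))
    return out


# ---------------------------------------------------------------------------
# Microsynteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyAnchor:
    """A homology anchor between gene ordinal positions of two regions."""

    a_index: int
    b_index: int
    score: float = 1.0
    strand: str = "+"

    def __post_init__(self):
        if self.a_index < 0 or self.b_index < 0:
            raise ValueError("anchor indices must be >= 0")
        if self.score < 0:
            raise ValueError("anchor score must be >= 0")


@dataclass
class SyntenyBlock:
    anchors: list
    orientation: str  # "forward" | "inverted"

    @property
    def score(self) -> float:
        return sum(a.score for a in self.anchors)

    def __len__(self):
        return len(self.anchors)


def _best_chain(anchors: list[SyntenyAnchor], max_gap: int) -> list[int]:
    """Max-score chain monotonically increasing in both axes with at most
    ``max_gap`` skipped indices between consecutive anchors, by weighted
    longest-increasing-subsequence DP. Returns anchor indices."""
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].a_index, anchors[i].b_index))
    best = [anchors[i].score for i in order]
    back = [-1] * len(order)
    for u in range(len(order)):
        au = anchors[order[u]]
        for v in range(u):
            av = anchors[order[v]]
            if (av.a_index < au.a_index and av.b_index < au.b_index
                    and au.a_index - av.a_index - 1 <= max_gap
                    and au.b_index - av.b_index - 1 <= max_gap):
                cand = best[v] + anchors[order[u]].score
                if cand > best[u]:
                    best[u] = cand
                    back[u] = v
    if not best:
        return []
    end = max(range(len(best)), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(order[end])
        end = back[end]
    return chain[::-1]


def microsynteny_chain(anchors: Sequence[SyntenyAnchor], max_gap: int = 5,
                       min_block: int = 3) -> list[SyntenyBlock]:
    """Collinear blocks from deduplicated anchors.

    Forward blocks are monotone increasing in both regions; inversion blocks
    are monotone decreasing in region B (found by chaining on the reflected
    B axis). Chains are extracted best-first; anchors belong to at most one
    block; chains shorter than ``min_block`` are discarded.
    """
    blocks: list[SyntenyBlock] = []
    remaining = list(anchors)
    while True:
        candidates = []
        if remaining:
            fwd = _best_chain(remaining, max_gap)
            if len(fwd) >= min_block:
                candidates.append(("forward", fwd))
            bmax = max(a.b_index for a in remaining)
            mirrored = [SyntenyAnchor(a.a_index, bmax - a.b_index, a.score,
                                      a.strand) for a in remaining]
            inv = _best_chain(mirrored, max_gap)
            if len(inv) >= min_block:
                candidates.append(("inverted", inv))
        if not candidates:
            break
        orientation, idx = max(
            candidates, key=lambda c: sum(remaining[i].score for i in c[1]))
        blocks.append(SyntenyBlock([remaining[i] for i in idx], orientation))
        used = set(idx)
        remaining = [a for i, a in enumerate(remaining) if i not in used]
    return blocks


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for bi, block in enumerate(blocks):
        for a in block.anchors:
            rows.append({"block": bi, "orientation": block.orientation,
                         "a_index": a.a_index, "b_index": a.b_index,
                         "score": a.score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _match_positions(template: str, primer: str, max_mismatch: int) -> list[int]:
    hits = []
    m = len(primer)
    for i in range(len(template) - m + 1):
        window = template[i:i + m]
        mism = sum(1 for a, b in zip(window, primer) if a != b)
        if mism <= max_mismatch:
            hits.append(i)
    return hits


def insilico_pcr(template: str, fwd_primer: str, rev_primer: str,
                 max_mismatch: int = 0, max_product: int = 5000) -> list[tuple]:
    """Predict PCR products on the plus strand of ``template``.

    The forward primer anneals on the plus strand, the reverse primer on the
    minus strand (its reverse complement is searched downstream). Returns
    (start, end, product_length) triples, 0-based with ``end`` exclusive,
    sorted by start; the product includes both primers.
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be >= 15 nt")
    template = template.upper()
    fwd_sites = _match_positions(template, fwd_primer.upper(), max_mismatch)
    rev_sites = _match_positions(template, reverse_complement(rev_primer),
                                 max_mismatch)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_primer)
            if end - f >= len(fwd_primer) + len(rev_primer) and r > f \
                    and end - f <= max_product:
                products.append((f, end, end - f))
    return sorted(products)
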