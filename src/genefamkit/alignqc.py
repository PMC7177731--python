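"""Alignment quality control.

Gap-pattern outlier rejection (sequences whose gap placement differs markedly
from the rest of the alignment are usually truncated gene models, assembly
errors, or pseudogenes), occupancy-based column trimming, back-translation of
protein alignments to codons, and masking of codon columns that are rare
within a clade (applied before selection analyses so that sparsely occupied
columns cannot drive the likelihood).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np

from . import codonmodel as cm
from .alignments import CodonAlignment

logger = logging.getLogger(__name__)


def gap_distance_matrix(aln: CodonAlignment) -> np.ndarray:
    """Pairwise Hamming distances between the binary gap masks of all rows.

    Returns a symmetric (n, n) matrix with zero diagonal.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    masks = aln.gap_mask().astype(np.int64)
    # Hamming distance between 0/1 vectors via inner products.
    same = masks @ masks.T + (1 - masks) @ (1 - masks.T)
    return (aln.n_columns - same).astype(float)


def detect_outliers(D: np.ndarray, z_threshold: float = 2.5) -> list[int]:
    """Flag sequences with an unusually large mean gap distance to the rest.

    Sequence i is flagged when its mean distance to all others exceeds
    mean + z_threshold * sd of the per-sequence mean distances, the reference
    statistics being computed with i excluded (so a gross outlier cannot mask
    itself). A single pass is made.

    Returns indices into the matrix; callers map these back to sequence ids.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 4:
        warnings.warn("fewer than 4 sequences: outlier detection skipped")
        return []
    means = D.sum(axis=1) / (n - 1)
    flagged = []
    for i in range(n):
        others = np.delete(means, i)
        mu, sd = others.mean(), others.std(ddof=1)
        if means[i] > mu + z_threshold * sd:
            flagged.append(i)
    return flagged


def flag_gap_outliers(aln: CodonAlignment, z_threshold: float = 2.5) -> list[str]:
    """Convenience wrapper: gap distances + outlier rule, returning ids."""
    if aln.n_sequences < 4:
        warnings.warn("fewer than 4 sequences: outlier detection skipped")
        return []
    idx = detect_outliers(gap_distance_matrix(aln), z_threshold)
    return [aln.ids[i] for i in idx]


def trim_by_occupancy(aln: CodonAlignment, min_occupancy: float) -> CodonAlignment:
    """Remove codon columns whose non-gap fraction is below ``min_occupancy``.

    Columns are removed in whole codon triples so the reading frame of every
    row is preserved. The conventional presets are 0.70 (strict, for species
    tree supermatrices) and 0.01 (permissive, drops only near-empty columns).
    """
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    occ = aln.codon_occupancy()
    keep = occ >= min_occupancy
    if not keep.any():
        raise ValueError("alignment fully trimmed: no codon column reaches "
                         f"occupancy {min_occupancy}")
    out = aln.select_codon_columns(keep)
    out.meta["trimmed_columns"] = int((~keep).sum())
    return out


def mask_rare_codon_columns(aln: CodonAlignment, clade_members: Iterable[str],
                            min_frac: float = 0.30) -> CodonAlignment:
    """Remove codon columns present in fewer than ``min_frac`` of the clade.

    The rule is strict "less than": a column occupied in exactly
    ``min_frac`` of the clade members is retained.
    """
    clade = list(clade_members)
    if not clade:
        raise ValueError("empty clade")
    missing = [c for c in clade if c not in aln.ids]
    if missing:
        raise ValueError(f"clade members absent from alignment: {missing}")
    occ = aln.codon_occupancy(clade)
    keep = occ >= min_frac
    if not keep.any():
        raise ValueError("all codon columns are rare within the clade")
    out = aln.select_codon_columns(keep)
    out.meta["masked_columns"] = int((~keep).sum())
    return out


def backtranslate(protein_aln: Mapping[str, str] | CodonAlignment,
                  cds_map: Mapping[str, str]) -> CodonAlignment:
    """Map a protein alignment back onto its source coding sequences.

    Every residue is replaced by the codon that encodes it in the unaligned
    CDS; every protein gap becomes ``---``. A terminal stop codon on the CDS
    is stripped (CDS lengths conventionally include the stop, protein lengths
    do not); an internal stop is a hard error, as is any residue that the CDS
    codon does not encode.
    """
    if isinstance(protein_aln, CodonAlignment):  # pragma: no cover - defensive
        raise TypeError("protein_aln must map id -> aligned protein string")
    ids, rows = [], []
    for sid, prot in protein_aln.items():
        if sid not in cds_map:
            raise ValueError(f"no CDS for {sid}")
        cds = cds_map[sid].upper().replace("U", "T")
        if len(cds) % 3:
            raise ValueError(f"{sid}: CDS length not divisible by 3")
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in cm.STOP_CODONS:
            logger.info("%s: terminal stop codon stripped before back-translation", sid)
            codons = codons[:-1]
        residues = prot.replace("-", "")
        if len(residues) != len(codons):
            raise ValueError(
                f"{sid}: protein has {len(residues)} residues but CDS has "
                f"{len(codons)} codons (after stop stripping)")
        for pos, (aa, codon) in enumerate(zip(residues, codons), start=1):
            if codon in cm.STOP_CODONS:
                raise ValueError(f"{sid}: internal stop codon at residue {pos}")
            coded = cm.translate_codon(codon)
            if coded != aa.upper():
                raise ValueError(
                    f"{sid}: residue {pos} is {aa} but codon {codon} encodes {coded}")
        it = iter(codons)
        rows.append("".join("---" if aa == "-" else next(it) for aa in prot))
        ids.append(sid)
    return CodonAlignment(ids, rows)
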