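"""Pairwise Ka/Ks by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction of
single-nucleotide changes at each position that preserve the amino acid
(changes to stop codons are excluded and the fraction renormalised, so every
codon contributes exactly 3 sites and N + S = 3 x codons). Observed
*differences* between codons separated by more than one nucleotide are
averaged over all shortest mutational pathways, excluding pathways that pass
through a stop codon (all pathways are used if every one is blocked). The
proportions pN = Nd/N and pS = Sd/S are Jukes-Cantor corrected,
d = -(3/4) ln(1 - 4p/3); p >= 3/4 is reported as saturated (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import pandas as pd

from . import codonmodel as cm
from .alignments import CodonAlignment


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float  # NaN when Ks = 0 or either rate is saturated
    N: float
    S: float
    Nd: float
    Sd: float
    n_codons: int
    flags: list = field(default_factory=list)


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon."""
    aa = cm.translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + n + codon[pos + 1:]
                for n in "TCAG" if n != codon[pos]]
        valid = [a for a in alts if a not in cm.STOP_CODONS]
        if not valid:
            continue
        syn += sum(1 for a in valid if cm.translate_codon(a) == aa) / len(valid)
    return syn, 3.0 - syn


_SITE_COUNTS = {c: _codon_site_counts(c) for c in cm.CODONS}


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over shortest mutational pathways."""
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in cm.STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        syn = sum(1 for a, b in steps
                  if cm.GENETIC_CODE[a] == cm.GENETIC_CODE[b]
                  and a not in cm.STOP_CODONS and b not in cm.STOP_CODONS)
        nonsyn = len(steps) - syn
        paths.append((blocked, syn, nonsyn))
    open_paths = [(s, n) for blocked, s, n in paths if not blocked]
    if not open_paths:  # every pathway crosses a stop; fall back to all
        open_paths = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in open_paths) / len(open_paths)
    nonsyn = sum(n for _, n in open_paths) / len(open_paths)
    return syn, nonsyn


def _jc_correct(p: float) -> float:
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds1: str, cds2: str) -> KaKsResult:
    """NG86 Ka/Ks for two in-frame coding sequences of equal length.

    Codons where either sequence has a gap or ambiguity are removed pairwise;
    internal stop codons are an error.
    """
    s1 = cds1.upper().replace("U", "T")
    s2 = cds2.upper().replace("U", "T")
    if len(s1) != len(s2):
        raise ValueError("sequences differ in length")
    if len(s1) % 3:
        raise ValueError("length not divisible by 3")
    codon_pairs = []
    for i in range(0, len(s1), 3):
        a, b = s1[i:i + 3], s2[i:i + 3]
        if a in cm.STOP_CODONS or b in cm.STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i // 3}")
        if a in cm.CODON_INDEX and b in cm.CODON_INDEX:
            codon_pairs.append((a, b))

    S = N = Sd = Nd = 0.0
    for a, b in codon_pairs:
        sa, na = _SITE_COUNTS[a]
        sb, nb = _SITE_COUNTS[b]
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _pathway_differences(a, b)
        Sd += ds
        Nd += dn

    flags = []
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jc_correct(pS)
    ka = _jc_correct(pN)
    if math.isnan(ks):
        flags.append("ks_saturated")
    if math.isnan(ka):
        flags.append("ka_saturated")
    if math.isnan(ka) or math.isnan(ks) or ks == 0:
        ratio = math.nan
        if ks == 0 and not flags:
            flags.append("ks_zero")
    else:
        ratio = ka / ks
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, N=N, S=S, Nd=Nd, Sd=Sd,
                      n_codons=len(codon_pairs), flags=flags)


def classify_ratio(ratio: float, purifying_below: float = 0.5,
                   positive_above: float = 1.5) -> str:
    """Band a Ka/Ks ratio: purifying (< 0.5), neutral ([0.5, 1.5]),
    positive (> 1.5). Thresholds are artifact conventions (a ratio near
    0.87 is conventionally called neutral), configurable by the caller."""
    if math.isnan(ratio):
        return "undefined"
    if ratio < purifying_below:
        return "purifying"
    if ratio > positive_above:
        return "positive"
    return "neutral"


def kaks_pair_table(aln: CodonAlignment, pairs: Sequence[tuple[str, str]],
                    purifying_below: float = 0.5,
                    positive_above: float = 1.5) -> pd.DataFrame:
    """NG86 Ka/Ks for a list of id pairs from one codon alignment.

    Each pair is degapped pairwise (codon columns gapped in either row are
    dropped) before counting.
    """
    rows = []
    for a, b in pairs:
        res = ng86_kaks(aln.row(a), aln.row(b))
        rows.append({
            "seq1": a, "seq2": b, "ka": res.ka, "ks": res.ks,
            "ratio": res.ratio, "N": res.N, "S": res.S,
            "Nd": res.Nd, "Sd": res.Sd, "n_codons": res.n_codons,
            "classification": classify_ratio(res.ratio, purifying_below,
                                             positive_above),
        })
    return pd.DataFrame(rows)
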