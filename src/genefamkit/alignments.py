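"""Codon alignment container and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import codonmodel as cm


@dataclass
class CodonAlignment:
    """Aligned coding sequences with codon-column structure.

    Rows are strings over {A, C, G, T, -} of a common length divisible by 3.
    Gaps introduced by back-translation come in multiples of 3, so the codon
    frame is preserved for every row.
    """

    ids: list[str]
    rows: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("ragged alignment: rows differ in length")
            if L % 3:
                raise ValueError("alignment length not divisible by 3")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.n_columns // 3

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    # -- matrix views ------------------------------------------------------
    def char_matrix(self) -> np.ndarray:
        """(n_sequences, n_columns) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def gap_mask(self) -> np.ndarray:
        """Boolean (n_sequences, n_columns); True where the residue is a gap."""
        return self.char_matrix() == "-"

    def codon_state_matrix(self) -> np.ndarray:
        """(n_sequences, n_codons) sense-codon indices; -1 for any codon
        containing a gap or ambiguity character."""
        out = np.empty((self.n_sequences, self.n_codons), dtype=np.int64)
        for i, r in enumerate(self.rows):
            for j in range(self.n_codons):
                codon = r[3 * j:3 * j + 3]
                out[i, j] = cm.CODON_INDEX.get(codon, -1)
        return out

    def codon_occupancy(self, ids: Sequence[str] | None = None) -> np.ndarray:
        """Per-codon-column fraction of (selected) rows whose codon is fully
        ungapped."""
        idx = range(self.n_sequences) if ids is None else [self.ids.index(i) for i in ids]
        idx = list(idx)
        if not idx:
            raise ValueError("empty sequence selection")
        gaps = self.gap_mask()[idx]
        codon_gapped = gaps.reshape(len(idx), self.n_codons, 3).any(axis=2)
        return 1.0 - codon_gapped.mean(axis=0)

    # -- editing -----------------------------------------------------------
    def select_codon_columns(self, keep: np.ndarray) -> "CodonAlignment":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        rows = ["".join(r[3 * j:3 * j + 3] for j in keep) for r in self.rows]
        return CodonAlignment(list(self.ids), rows, dict(self.meta))

    def drop_sequences(self, ids: Iterable[str]) -> "CodonAlignment":
        drop = set(ids)
        keep = [i for i, sid in enumerate(self.ids) if sid not in drop]
        return CodonAlignment([self.ids[i] for i in keep],
                              [self.rows[i] for i in keep], dict(self.meta))

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        return CodonAlignment(list(ids), [self.row(i) for i in ids], dict(self.meta))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(r), id=i, description="")
                   for i, r in zip(self.ids, self.rows)]
        SeqIO.write(records, str(path), "fasta")

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")
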