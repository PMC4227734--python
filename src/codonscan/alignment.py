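"""In-frame codon alignments.

A :class:`CodonAlignment` holds one ortholog family: equal-length, in-frame
nucleotide sequences for an ordered set of taxa.  Gaps come only in whole
codons (``---``); partially gapped codons violate the in-frame contract and
are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genetics


@dataclass
class CodonAlignment:
    taxa: list[str]
    sequences: list[str]
    gene_id: str = ""
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths in {self.gene_id or 'alignment'}")
        if lengths and lengths.pop() % 3 != 0:
            raise ValueError("aligned length is not a multiple of 3")
        for taxon, seq in zip(self.taxa, self.sequences):
            for codon in genetics.codons_of(seq):
                n_gap = codon.count("-")
                if n_gap not in (0, 3):
                    raise ValueError(f"partially gapped codon {codon!r} in {taxon}")

    # -- geometry ----------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    @property
    def length_nt(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def codon_matrix(self) -> np.ndarray:
        """(n_taxa, n_codons) sense-codon indices; -1 = gap/ambiguous/stop."""
        if self._matrix is None:
            self._matrix = np.vstack([genetics.encode_codons(s) for s in self.sequences])
        return self._matrix

    def seq_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def select_columns(self, keep: np.ndarray) -> "CodonAlignment":
        """New alignment keeping the codon columns where ``keep`` is True."""
        cols = np.flatnonzero(np.asarray(keep, dtype=bool))
        seqs = ["".join(s[3 * c : 3 * c + 3] for c in cols) for s in self.sequences]
        return CodonAlignment(list(self.taxa), seqs, gene_id=self.gene_id)

    def third_positions(self) -> list[str]:
        """Third-codon-position nucleotide strings, one per taxon."""
        return ["".join(s[2::3]) for s in self.sequences]

    def concatenate(self, other: "CodonAlignment") -> "CodonAlignment":
        if self.taxa != other.taxa:
            raise ValueError(
                f"taxon sets differ between {self.gene_id or '?'} and {other.gene_id or '?'}"
            )
        return CodonAlignment(
            list(self.taxa),
            [a + b for a, b in zip(self.sequences, other.sequences)],
            gene_id=self.gene_id,
        )

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path, gene_id: str | None = None) -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        taxa = [r.id.split("|")[0] for r in records]
        seqs = [str(r.seq).upper() for r in records]
        return cls(taxa, seqs, gene_id=gene_id or Path(path).stem)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=f"{taxon}|{self.gene_id}" if self.gene_id else taxon, description="")
            for taxon, seq in zip(self.taxa, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


def concatenate_alignments(alignments: list[CodonAlignment], gene_id: str = "concat") -> CodonAlignment:
    """Concatenate codon columns gene-by-gene; taxon sets must agree."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = alignments[0].taxa
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    for aln in alignments:
        if aln.taxa != taxa:
            raise ValueError(f"gene {aln.gene_id or '?'} has a different taxon set")
        for t, s in zip(aln.taxa, aln.sequences):
            parts[t].append(s)
    return CodonAlignment(list(taxa), ["".join(parts[t]) for t in taxa], gene_id=gene_id)
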