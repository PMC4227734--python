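"""Standard nuclear genetic code and codon bookkeeping.

The 61 sense codons of the standard code are the state space of every codon
model in this package.  Codons are ordered lexicographically over the
nucleotide alphabet ``A < C < G < T`` with the three stop codons removed, and
all model matrices index into that fixed order.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_standard.stop_codons))
ALL_CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

#: transitions are A<->G and C<->T
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _single_step_pairs():
    """Index arrays over all ordered sense-codon pairs differing at one site."""
    rows, cols, transition, synonymous = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            rows.append(i)
            cols.append(j)
            transition.append(is_transition(ci[k], cj[k]))
            synonymous.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(transition, dtype=bool),
        np.asarray(synonymous, dtype=bool),
    )


PAIR_ROWS, PAIR_COLS, PAIR_IS_TRANSITION, PAIR_IS_SYNONYMOUS = _single_step_pairs()


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; ambiguous codons become ``X``."""
    return str(Seq(seq).translate())


def codons_of(seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def encode_codons(seq: str) -> np.ndarray:
    """Map an in-frame nucleotide string to sense-codon indices.

    Gap codons (``---``), codons containing ambiguity characters and stop
    codons are encoded as ``-1`` (missing data for the likelihood engine).
    """
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k, codon in enumerate(codons_of(seq.upper())):
        out[k] = CODON_INDEX.get(codon, -1)
    return out


def decode_codons(states: np.ndarray) -> str:
    return "".join(SENSE_CODONS[s] if s >= 0 else "---" for s in states)


def equal_codon_frequencies() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_frequencies(seqs: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts.

    Counts nucleotides separately at the three codon positions over all
    sequences (gaps and ambiguity characters skipped), forms codon
    frequencies as the product of positional frequencies, zeroes the stop
    codons and renormalises.  A pseudocount keeps every sense codon strictly
    positive, which the reversible-matrix eigendecomposition requires.
    """
    counts = np.full((3, 4), pseudocount, dtype=float)
    for seq in seqs:
        s = seq.upper()
        for pos in range(0, len(s) - 2, 3):
            for k in range(3):
                idx = NT_INDEX.get(s[pos + k])
                if idx is not None:
                    counts[k, idx] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, NT_INDEX[c[0]]] * freqs[1, NT_INDEX[c[1]]] * freqs[2, NT_INDEX[c[2]]] for c in SENSE_CODONS]
    )
    return pi / pi.sum()


def has_internal_stop(seq: str) -> bool:
    """True if any non-terminal codon of an in-frame sequence is a stop."""
    codons = codons_of(seq.upper())
    return any(c in STOP_CODONS for c in codons[:-1]) if codons else False
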