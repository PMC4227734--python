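"""1:1 ortholog determination by translated best reciprocal hits.

Transcripts are compared to a reference CDS set with a translated local
Smith-Waterman search: all six reading frames of the query against the
three forward frames of the target, BLOSUM62 scoring, affine gaps, and stop
codons made prohibitively expensive inside an aligned block (tBlastx-like
behaviour).  A transcript/CDS pair is called an ortholog only when each is
the unique best hit of the other and both scores clear a significance
threshold; significance is calibrated on shuffled-sequence nulls rather
than by BLAST e-value statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_FRAMES = (1, 2, 3, -1, -2, -3)


def _make_aligner(gap_open: float, gap_extend: float, stop_score: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.load("BLOSUM62")
    arr = np.array(matrix)
    alphabet = matrix.alphabet
    stop = alphabet.index("*")
    arr[stop, :] = stop_score
    arr[:, stop] = stop_score
    aligner.substitution_matrix = substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _frame_translation(seq: str, frame: int) -> str:
    s = seq if frame > 0 else str(Seq(seq).reverse_complement())
    offset = abs(frame) - 1
    usable = (len(s) - offset) // 3 * 3
    if usable <= 0:
        return ""
    return str(Seq(s[offset : offset + usable]).translate())


@dataclass
class AlignmentHit:
    """Best translated local alignment between two nucleotide sequences."""

    query_id: str
    target_id: str
    score: float
    query_frame: int
    target_frame: int
    query_span: tuple[int, int]  # 0-based half-open, nucleotide coords on input
    target_span: tuple[int, int]


@dataclass
class OrthologPair:
    transcript_id: str
    cds_id: str
    forward_score: float
    reciprocal_score: float


class TranslatedSearch:
    """Reusable translated-alignment scorer with per-sequence frame caching."""

    def __init__(self, gap_open: float = 11.0, gap_extend: float = 1.0, stop_score: float = -1000.0):
        self.aligner = _make_aligner(gap_open, gap_extend, stop_score)
        self._frames: dict[tuple[str, bool], list[tuple[int, str]]] = {}

    def frames(self, seq: str, six: bool = True) -> list[tuple[int, str]]:
        key = (seq, six)
        hit = self._frames.get(key)
        if hit is None:
            frames = _FRAMES if six else (1, 2, 3)
            hit = [(f, _frame_translation(seq, f)) for f in frames]
            hit = [(f, p) for f, p in hit if p]
            self._frames[key] = hit
            if len(self._frames) > 4096:
                self._frames.clear()
        return hit

    def score(self, query: str, target: str) -> float:
        """Best peptide-level score over query six-frames x target forward frames."""
        best = 0.0
        for _, pq in self.frames(query, six=True):
            for _, pt in self.frames(target, six=False):
                s = self.aligner.score(pq, pt)
                if s > best:
                    best = s
        return best


def translated_similarity(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    search: TranslatedSearch | None = None,
) -> AlignmentHit:
    """Maximum-scoring translated local alignment over all frame pairs.

    Coordinates in the returned hit are 0-based half-open nucleotide
    positions on the input strings (for negative query frames the span is
    mapped back to the forward strand).  An all-N or frame-less sequence
    yields a hit with score 0.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    search = search or TranslatedSearch(gap_open, gap_extend)
    best = AlignmentHit(query_id, target_id, 0.0, 1, 1, (0, 0), (0, 0))
    for fq, pq in search.frames(query, six=True):
        for ft, pt in search.frames(target, six=False):
            score = search.aligner.score(pq, pt)
            if score <= best.score:
                continue
            alignment = search.aligner.align(pq, pt)[0]
            qs, qe = int(alignment.aligned[0][0][0]), int(alignment.aligned[0][-1][1])
            ts, te = int(alignment.aligned[1][0][0]), int(alignment.aligned[1][-1][1])
            off_q = abs(fq) - 1
            nt_qs, nt_qe = off_q + 3 * qs, off_q + 3 * qe
            if fq < 0:
                nt_qs, nt_qe = len(query) - nt_qe, len(query) - nt_qs
            off_t = ft - 1
            best = AlignmentHit(
                query_id, target_id, float(score), fq, ft,
                (nt_qs, nt_qe), (off_t + 3 * ts, off_t + 3 * te),
            )
    return best


def _shuffle(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    return b"".join(rng.permutation(arr)).decode()


def calibrate_min_score(
    transcripts: dict[str, str],
    reference_cds: dict[str, str],
    n_shuffles: int = 10_000,
    quantile: float = 0.99999,
    seed: int = 0,
    search: TranslatedSearch | None = None,
) -> float:
    """Score threshold from shuffled-sequence null pairs.

    Draws random (transcript, CDS) pairs, shuffles both members to destroy
    homology while keeping length and composition, aligns them, and returns
    the requested upper quantile of the null score distribution.
    """
    rng = np.random.default_rng(seed)
    search = search or TranslatedSearch()
    t_ids = sorted(transcripts)
    c_ids = sorted(reference_cds)
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        t = transcripts[t_ids[int(rng.integers(len(t_ids)))]]
        c = reference_cds[c_ids[int(rng.integers(len(c_ids)))]]
        scores[k] = search.score(_shuffle(t, rng), _shuffle(c, rng))
    return float(np.quantile(scores, quantile))


def _kmer_set(peptide: str, k: int = 5) -> set[str]:
    return {peptide[i : i + k] for i in range(len(peptide) - k + 1)}


def best_reciprocal_hits(
    transcripts: dict[str, str],
    reference_cds: dict[str, str],
    min_score: float,
    min_hit_fraction: float = 0.3,
    prefilter_kmers: int = 1,
    search: TranslatedSearch | None = None,
) -> tuple[list[OrthologPair], list[str]]:
    """Reciprocal-best 1:1 ortholog pairs between two sequence sets.

    A pair is emitted iff each member is the unique top-scoring hit of the
    other, both directions score at least ``min_score``, and the alignment
    covers at least ``min_hit_fraction`` of the shorter translated length.
    Ties for best hit drop the sequence (returned in the tie log) — only
    unambiguous 1:1 orthologs survive.  ``prefilter_kmers`` skips full
    alignment of pairs sharing fewer than that many peptide 5-mers across
    frames (0 disables the screen).
    """
    if not transcripts or not reference_cds:
        raise ValueError("both sequence sets must be non-empty")
    search = search or TranslatedSearch()
    t_ids = sorted(transcripts)
    c_ids = sorted(reference_cds)
    t_kmers = {t: set().union(*(_kmer_set(p) for _, p in search.frames(transcripts[t], six=True))) for t in t_ids}
    c_kmers = {c: set().union(*(_kmer_set(p) for _, p in search.frames(reference_cds[c], six=False))) for c in c_ids}

    scores = np.zeros((len(t_ids), len(c_ids)))
    for i, t in enumerate(t_ids):
        for j, c in enumerate(c_ids):
            if prefilter_kmers and len(t_kmers[t] & c_kmers[c]) < prefilter_kmers:
                continue
            scores[i, j] = search.score(transcripts[t], reference_cds[c])

    dropped: list[str] = []
    best_for_t = {}
    for i, t in enumerate(t_ids):
        row = scores[i]
        j = int(row.argmax())
        if row[j] < min_score:
            continue
        if (row == row[j]).sum() > 1:
            dropped.append(f"{t}: tie for best hit")
            continue
        best_for_t[i] = j
    best_for_c = {}
    for j, c in enumerate(c_ids):
        col = scores[:, j]
        i = int(col.argmax())
        if col[i] < min_score:
            continue
        if (col == col[i]).sum() > 1:
            dropped.append(f"{c}: tie for best hit")
            continue
        best_for_c[j] = i

    pairs: list[OrthologPair] = []
    for i, j in best_for_t.items():
        if best_for_c.get(j) != i:
            continue
        t, c = t_ids[i], c_ids[j]
        min_len = min(len(transcripts[t]), len(reference_cds[c])) // 3
        hit = translated_similarity(transcripts[t], reference_cds[c], t, c, search=search)
        aligned_aa = (hit.query_span[1] - hit.query_span[0]) // 3
        if min_len > 0 and aligned_aa / min_len < min_hit_fraction:
            dropped.append(f"{t}~{c}: hit fraction {aligned_aa / min_len:.2f} below {min_hit_fraction}")
            continue
        pairs.append(OrthologPair(t, c, float(scores[i, j]), float(scores[i, j])))
    for msg in dropped:
        logger.info("BRH drop: %s", msg)
    return pairs, dropped


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_pairs_tsv(pairs: list[OrthologPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcds_id\tfwd_score\trev_score\n")
        for p in pairs:
            fh.write(f"{p.transcript_id}\t{p.cds_id}\t{p.forward_score:g}\t{p.reciprocal_score:g}\n")
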