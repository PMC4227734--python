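"""Nei-Gojobori style pairwise Ka/Ks by site counting.

A deliberately simple counting method kept alongside the likelihood fits as
an independent cross-check: synonymous/nonsynonymous site fractions per
codon, averaged path counting of observed differences, and the Jukes-Cantor
multiple-hit correction.  Site counting optionally weights transitions by a
transition/transversion ratio ``kappa`` (the unweighted ``kappa = 1`` case
is the classic NG86 count, which is biased when the mutation process is
transition-rich).  Codon pairs involving gaps, ambiguity characters or stop
codons are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .. import genetics

_SENSE = set(genetics.SENSE_CODONS)


@lru_cache(maxsize=512)
def _syn_sites(codon: str, kappa: float) -> float:
    """Synonymous site count of one codon out of its 3 positions.

    Each position contributes ``3 * (weighted synonymous changes) /
    (weighted total changes)`` sites in total across the codon; changes to
    stop codons count as nonsynonymous opportunity.  Transitions carry
    weight ``kappa``.
    """
    aa = genetics.CODON_AA[genetics.CODON_INDEX[codon]]
    syn_w = tot_w = 0.0
    for k in range(3):
        for b in genetics.NUCLEOTIDES:
            if b == codon[k]:
                continue
            w = kappa if genetics.is_transition(codon[k], b) else 1.0
            tot_w += w
            alt = codon[:k] + b + codon[k + 1 :]
            if alt in _SENSE and genetics.CODON_AA[genetics.CODON_INDEX[alt]] == aa:
                syn_w += w
    return 3.0 * syn_w / tot_w


def _path_counts(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over minimal paths."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diffs):
        cur = a
        syn = non = 0
        through_stop = False
        for k in order:
            nxt = cur[:k] + b[k] + cur[k + 1 :]
            if nxt not in _SENSE:
                through_stop = True
                break
            if genetics.CODON_AA[genetics.CODON_INDEX[cur]] == genetics.CODON_AA[genetics.CODON_INDEX[nxt]]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if not through_stop:
            valid.append((syn, non))
        fallback.append((syn, non))
    paths = valid or fallback
    syn = float(np.mean([p[0] for p in paths]))
    non = float(np.mean([p[1] for p in paths]))
    # fallback paths truncated at a stop undercount; rescale to the number
    # of differing positions
    total = syn + non
    if total > 0 and not np.isclose(total, len(diffs)):
        scale = len(diffs) / total
        syn, non = syn * scale, non * scale
    return syn, non


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseRates:
    ka: float
    ks: float
    ratio: float
    n_sites: float
    s_sites: float


def ng86_pairwise(seq_a: str, seq_b: str, kappa: float = 1.0) -> PairwiseRates:
    """Counting Ka, Ks and dN/dS for two equal-length in-frame sequences.

    Symmetric in its arguments.  A corrected proportion at or beyond the
    Jukes-Cantor saturation bound (p >= 0.75) yields NaN markers.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    codons_a = genetics.codons_of(seq_a.upper())
    codons_b = genetics.codons_of(seq_b.upper())
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca not in _SENSE or cb not in _SENSE:
            continue
        s_avg = 0.5 * (_syn_sites(ca, kappa) + _syn_sites(cb, kappa))
        S += s_avg
        N += 3.0 - s_avg
        syn, non = _path_counts(ca, cb)
        Sd += syn
        Nd += non
    if S == 0 or N == 0:
        return PairwiseRates(float("nan"), float("nan"), float("nan"), N, S)
    ks = _jc_correct(Sd / S)
    ka = _jc_correct(Nd / N)
    ratio = ka / ks if (np.isfinite(ka) and np.isfinite(ks) and ks > 0) else float("nan")
    return PairwiseRates(ka=ka, ks=ks, ratio=ratio, n_sites=N, s_sites=S)
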