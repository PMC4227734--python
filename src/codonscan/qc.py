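"""Codon-alignment quality control.

Four stages mirror the dataset-construction filters of a comparative
positive-selection scan:

* consensus calling from per-site read-support counts (modal base);
* block trimming of unreliable alignment regions (a simplified,
  documented stand-in for Gblocks' ``codons`` mode);
* removal of genes with internal stop codons or trimmed length < 200 bp;
* a substitution-saturation screen: GTR branch lengths fitted to the
  third codon positions on the fixed species topology, with any branch
  length >= 1 flagging the gene as saturated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import genetics
from .alignment import CodonAlignment
from .models import matrices
from .models.likelihood import compress_patterns, site_likelihoods
from .trees import PhyloTree

logger = logging.getLogger(__name__)

MIN_ALIGNMENT_BP = 200
SATURATION_THRESHOLD = 1.0

_NT = {b: i for i, b in enumerate(genetics.NUCLEOTIDES)}


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def consensus_call(per_site_counts) -> str:
    """Modal base per site from read-support counts.

    ``per_site_counts`` is a sequence of ``{base: count}`` mappings or an
    (n_sites, 4) array over A, C, G, T.  Ties break alphabetically
    (A < C < G < T); a site with no support at all becomes ``N``.
    """
    out = []
    for site in per_site_counts:
        if isinstance(site, dict):
            counts = np.zeros(4)
            for base, c in site.items():
                if c < 0 or int(c) != c:
                    raise ValueError("counts must be non-negative integers")
                if base.upper() in _NT:
                    counts[_NT[base.upper()]] += c
        else:
            counts = np.asarray(site, dtype=float)
            if counts.shape != (4,) or np.any(counts < 0):
                raise ValueError("each site needs 4 non-negative counts")
        if counts.sum() == 0:
            out.append("N")
        else:
            out.append(genetics.NUCLEOTIDES[int(counts.argmax())])  # argmax = first max = alphabetical
    return "".join(out)


# ---------------------------------------------------------------------------
# block trimming
# ---------------------------------------------------------------------------

def _column_ok(aln: CodonAlignment, col: int, max_gap_fraction: float) -> bool:
    codons = [s[3 * col : 3 * col + 3] for s in aln.sequences]
    n = len(codons)
    n_gap = sum(1 for c in codons if c == "---")
    if n_gap / n > max_gap_fraction:
        return False
    aas = [genetics.translate(c) for c in codons if c != "---"]
    if not aas:
        return False
    (_, top), = Counter(aas).most_common(1)
    return top / n >= 0.5


def trim_alignment_blocks(
    alignment: CodonAlignment,
    min_block: int = 5,
    max_gap_fraction: float = 0.0,
) -> CodonAlignment:
    """Keep maximal runs of >= ``min_block`` reliable codon columns.

    A column is reliable when its gap fraction is at most
    ``max_gap_fraction`` and at least half of the taxa share the majority
    amino acid.  Kept blocks are concatenated in order; the result may be
    empty (the length filter then removes the gene downstream).
    """
    ok = np.array([_column_ok(alignment, c, max_gap_fraction) for c in range(alignment.n_codons)])
    keep = np.zeros_like(ok)
    run_start = None
    for c in range(len(ok) + 1):
        good = c < len(ok) and ok[c]
        if good and run_start is None:
            run_start = c
        elif not good and run_start is not None:
            if c - run_start >= min_block:
                keep[run_start:c] = True
            run_start = None
    return alignment.select_columns(keep)


# ---------------------------------------------------------------------------
# stop-codon / length filter
# ---------------------------------------------------------------------------

def filter_orthologs(
    alignments: list[CodonAlignment],
    min_length_bp: int = MIN_ALIGNMENT_BP,
) -> tuple[list[CodonAlignment], list[tuple[str, str]]]:
    """Keep genes with no internal stop codon and length >= ``min_length_bp``."""
    kept: list[CodonAlignment] = []
    rejected: list[tuple[str, str]] = []
    for aln in alignments:
        stops = [t for t, s in zip(aln.taxa, aln.sequences) if genetics.has_internal_stop(s.replace("-", "") or s)]
        if stops:
            rejected.append((aln.gene_id, f"internal stop codon in {','.join(stops)}"))
        elif aln.length_nt < min_length_bp:
            rejected.append((aln.gene_id, f"trimmed length {aln.length_nt} bp < {min_length_bp} bp"))
        else:
            kept.append(aln)
    for gene, reason in rejected:
        logger.info("filtered %s: %s", gene, reason)
    return kept, rejected


# ---------------------------------------------------------------------------
# saturation screen
# ---------------------------------------------------------------------------

@dataclass
class SaturationVerdict:
    gene_id: str
    branch_lengths: dict[str, float]
    saturated: bool
    reason: str = ""

    @property
    def max_branch_length(self) -> float:
        return max(self.branch_lengths.values()) if self.branch_lengths else 0.0


@dataclass
class GTRFit:
    lengths: dict[int, float]
    exchangeabilities: np.ndarray
    pi: np.ndarray
    lnl: float
    converged: bool


def _encode_nt(seqs: list[str]) -> np.ndarray:
    out = np.full((len(seqs), len(seqs[0])), -1, dtype=np.int64)
    for i, s in enumerate(seqs):
        for j, b in enumerate(s.upper()):
            out[i, j] = _NT.get(b, -1)
    return out


def fit_gtr_branch_lengths(
    sequences: dict[str, str],
    tree: PhyloTree,
    n_starts: int = 3,
    maxiter: int = 120,
) -> GTRFit:
    """ML branch lengths under GTR+F on a fixed topology.

    Base frequencies are empirical (with a pseudocount); the five free
    exchangeabilities (GT fixed at 1) and all branch lengths are jointly
    optimised by bounded quasi-Newton from ``n_starts`` deterministic
    starting points.  Branch lengths are bounded in [1e-8, 50].
    """
    taxa = list(sequences)
    mat = _encode_nt([sequences[t] for t in taxa])
    patterns, weights = compress_patterns(mat)
    counts = np.full(4, 0.5)
    for i in range(4):
        counts[i] += (mat == i).sum()
    pi = counts / counts.sum()

    taxon_row = {t: i for i, t in enumerate(taxa)}
    leaf_rows = {leaf: taxon_row.get(tree.labels[leaf]) for leaf in tree.leaves}
    edges = tree.edges
    n = len(edges)

    variable = False
    for p in range(patterns.shape[1]):
        col = patterns[:, p]
        obs = np.unique(col[col >= 0])
        if obs.size > 1:
            variable = True
            break
    if not variable:
        return GTRFit({e: 0.0 for e in edges}, np.ones(6), pi, 0.0, True)

    bounds = [(np.log(1e-8), np.log(50.0))] * n + [(np.log(1e-3), np.log(1e3))] * 5

    def nll(x: np.ndarray) -> float:
        lengths = np.exp(x[:n])
        ex = np.concatenate([np.exp(x[n:]), [1.0]])
        spec = matrices.gtr_spectral(ex, pi)
        P_by_edge = {e: spec.transition_matrix(float(t)) for e, t in zip(edges, lengths)}
        L = site_likelihoods(tree, P_by_edge, patterns, leaf_rows, pi)
        return -float(weights @ np.log(np.maximum(L, 1e-300)))

    starts = [
        np.concatenate([np.full(n, np.log(0.1)), np.zeros(5)]),
        np.concatenate([np.full(n, np.log(0.5)), np.log([1, 4, 1, 1, 4])]),
        np.concatenate([np.full(n, np.log(0.02)), np.log([0.5, 2, 0.5, 0.5, 2])]),
    ][: max(n_starts, 1)]
    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
    return GTRFit(
        lengths=dict(zip(edges, np.exp(best.x[:n]))),
        exchangeabilities=np.concatenate([np.exp(best.x[n:]), [1.0]]),
        pi=pi,
        lnl=-float(best.fun),
        converged=bool(best.success),
    )


def saturation_test(
    alignment: CodonAlignment,
    tree: PhyloTree,
    threshold: float = SATURATION_THRESHOLD,
) -> SaturationVerdict:
    """Third-codon-position GTR saturation screen.

    Extracts the third positions, fits GTR+F branch lengths on the fixed
    species topology and flags the gene as saturated when any fitted branch
    length reaches ``threshold``.  A non-convergent optimisation flags the
    gene conservatively.
    """
    third = dict(zip(alignment.taxa, alignment.third_positions()))
    fit = fit_gtr_branch_lengths(third, tree)
    lengths = {tree.edge_label(e): float(t) for e, t in fit.lengths.items()}
    if not fit.converged:
        logger.warning("saturation test: optimizer non-convergence for %s", alignment.gene_id)
        return SaturationVerdict(alignment.gene_id, lengths, True, "optimizer non-convergence")
    saturated = max(lengths.values()) >= threshold
    return SaturationVerdict(alignment.gene_id, lengths, saturated, "max branch length" if saturated else "")
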