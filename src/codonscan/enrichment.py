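"""Over-representation analysis of positively selected genes.

Per functional term, the over-representation p-value is the one-tailed
hypergeometric tail; the default "EASE" mode is the conservative modified
Fisher test that removes one success before computing the tail.  Term
p-values are combined into a cluster enrichment score
``ES = -log10(geometric mean of member p-values)``; a category is called
over-represented when ES exceeds 1.3 (the -log10 0.05 landmark) and its
p-value is below 0.05, both strict.  Benjamini-Hochberg adjusted p-values
are reported alongside the raw ones; classification uses the raw p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ES_THRESHOLD = 1.3
ALPHA = 0.05


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # PSGs carrying the term
    n: int  # PSG list size
    K: int  # background genes carrying the term
    N: int  # background size
    p_fisher: float
    p_ease: float
    p_adjusted: float = 1.0
    members: list[str] = field(default_factory=list)

    def p(self, mode: str = "ease") -> float:
        return self.p_ease if mode == "ease" else self.p_fisher


@dataclass
class ClusterScore:
    cluster_id: str
    term_ids: list[str]
    es: float
    p: float  # representative p (minimum member p)
    over_represented: bool


def _tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_overrepresentation(
    psg_ids,
    background_ids,
    term_to_genes: dict[str, list[str]],
    mode: str = "ease",
) -> list[EnrichmentResult]:
    """Hypergeometric/EASE over-representation per term.

    EASE recomputes the tail with one success removed (floored at zero),
    which penalises terms supported by a single gene.  BH-adjusted
    p-values (of the selected mode) are filled in across terms.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    background = set(background_ids)
    psgs = set(psg_ids)
    if not psgs <= background:
        raise ValueError("PSG ids must be a subset of the background")
    N, n = len(background), len(psgs)
    results: list[EnrichmentResult] = []
    for term in sorted(term_to_genes):
        genes = set(term_to_genes[term]) & background
        K = len(genes)
        if K == 0:
            continue
        members = sorted(genes & psgs)
        k = len(members)
        p_fisher = _tail(k, N, K, n) if n else 1.0
        p_ease = _tail(k - 1, N, K, n) if n else 1.0
        results.append(EnrichmentResult(term, k, n, K, N, p_fisher, p_ease, members=members))
    if results:
        adjusted = multipletests([r.p(mode) for r in results], method="fdr_bh")[1]
        for r, p in zip(results, adjusted):
            r.p_adjusted = float(p)
    return results


def enrichment_score(p_values, cluster_id: str = "", term_ids=None) -> ClusterScore:
    """ES = -log10 geometric mean of the cluster's term p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("cluster has no p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.maximum(p, 1e-300)
    es = float(-np.mean(np.log10(p)))
    rep_p = float(p.min())
    return ClusterScore(
        cluster_id=cluster_id,
        term_ids=list(term_ids) if term_ids is not None else [],
        es=es,
        p=rep_p,
        over_represented=bool(es > ES_THRESHOLD and rep_p < ALPHA),
    )


def classify_over_represented(
    results: list[EnrichmentResult],
    clusters: dict[str, list[str]] | None = None,
    mode: str = "ease",
    es_threshold: float = ES_THRESHOLD,
    alpha: float = ALPHA,
) -> list[ClusterScore]:
    """Flag categories with ES > threshold and p < alpha (strict).

    ``clusters`` maps cluster id to member term ids; by default every term
    is its own cluster, so ES reduces to -log10 of the term's p-value.
    """
    by_term = {r.term_id: r for r in results}
    if clusters is None:
        clusters = {r.term_id: [r.term_id] for r in results}
    scores: list[ClusterScore] = []
    for cid in sorted(clusters):
        terms = [t for t in clusters[cid] if t in by_term]
        if not terms:
            continue
        ps = [by_term[t].p(mode) for t in terms]
        cs = enrichment_score(ps, cluster_id=cid, term_ids=terms)
        cs.over_represented = bool(cs.es > es_threshold and cs.p < alpha)
        scores.append(cs)
    return scores


def write_enrichment_tsv(results: list[EnrichmentResult], scores: list[ClusterScore], path, mode: str = "ease") -> None:
    flag = {s.cluster_id: s for s in scores}
    with open(path, "w") as fh:
        fh.write("term_id\tcount\tp\tp_adjusted\tES\tflag\n")
        for r in results:
            s = flag.get(r.term_id)
            es = s.es if s else float("nan")
            over = int(s.over_represented) if s else 0
            fh.write(f"{r.term_id}\t{r.k}\t{r.p(mode):.6g}\t{r.p_adjusted:.6g}\t{es:.3f}\t{over}\n")
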