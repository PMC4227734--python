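"""Lineage evolutionary-rate summaries and category-level acceleration tests.

Lineage means of Ka, Ks and Ka/Ks come from a single free-ratio fit of the
concatenated super-alignment (not from averaging per-gene estimates).  The
category test compares expected nonsynonymous substitution counts on the
two focal lineages: per functional term, member-gene counts are summed and
tested against the genome-wide proportion with an exact two-sided binomial
test, followed by a Holm step-down familywise correction.  Only categories
with more than 20 member orthologs are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .alignment import CodonAlignment, concatenate_alignments
from .models.fit import BranchRates, fit_free_ratio
from .trees import PhyloTree

logger = logging.getLogger(__name__)

MIN_CATEGORY_ORTHOLOGS = 21  # "more than 20 orthologs"


@dataclass
class LineageRateSummary:
    lineage: str
    mean_ka: float
    mean_ks: float
    mean_ka_ks: float  # the concatenated fit's branch omega
    n_genes: int
    n_codons: int


@dataclass
class CategoryRateResult:
    term_id: str
    n_genes: int
    n_a: int
    n_b: int
    total_a: int
    total_b: int
    p_raw: float
    p_holm: float
    accelerated: str | None


def concatenate_and_fit(
    alignments: list[CodonAlignment],
    tree: PhyloTree,
    focal_taxa: tuple[str, str] = ("vlangalii", "przewalskii"),
) -> dict[str, LineageRateSummary]:
    """Free-ratio fit of the gene-by-gene concatenation; per-lineage means.

    The reported mean Ka/Ks is the fitted omega of each focal terminal
    branch in the concatenated fit, not a ratio of the mean Ka and mean Ks.
    """
    concat = concatenate_alignments(alignments)
    rates = fit_free_ratio(concat, tree)
    out = {}
    for taxon in focal_taxa:
        if taxon not in rates:
            raise ValueError(f"focal taxon {taxon!r} has no terminal branch in the fit")
        br = rates[taxon]
        out[taxon] = LineageRateSummary(
            lineage=taxon,
            mean_ka=br.ka,
            mean_ks=br.ks,
            mean_ka_ks=br.omega,
            n_genes=len(alignments),
            n_codons=concat.n_codons,
        )
    return out


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def category_rate_test(
    term_to_genes: dict[str, list[str]],
    rates_a: dict[str, BranchRates],
    rates_b: dict[str, BranchRates],
    min_orthologs: int = MIN_CATEGORY_ORTHOLOGS,
) -> list[CategoryRateResult]:
    """Binomial acceleration test per functional category.

    ``rates_a`` / ``rates_b`` map gene id to the focal branch's
    :class:`BranchRates` for the two lineages; expected nonsynonymous
    counts (``n_hat``) are summed over category members, rounded half-even,
    and tested against the genome-wide proportion ``N_A / (N_A + N_B)``.
    Categories with fewer than ``min_orthologs`` analysed members are
    dropped (logged).
    """
    genes = sorted(set(rates_a) & set(rates_b))
    gene_set = set(genes)
    total_a = _round_half_even(sum(rates_a[g].n_hat for g in genes))
    total_b = _round_half_even(sum(rates_b[g].n_hat for g in genes))
    p0 = total_a / (total_a + total_b) if total_a + total_b > 0 else 0.5

    tested: list[CategoryRateResult] = []
    for term in sorted(term_to_genes):
        members = [g for g in term_to_genes[term] if g in gene_set]
        if len(members) < min_orthologs:
            logger.info("category %s dropped: %d orthologs < %d", term, len(members), min_orthologs)
            continue
        n_a = _round_half_even(sum(rates_a[g].n_hat for g in members))
        n_b = _round_half_even(sum(rates_b[g].n_hat for g in members))
        if n_a + n_b == 0:
            p_raw, accel = 1.0, None
        else:
            p_raw = float(binomtest(n_a, n_a + n_b, p0, alternative="two-sided").pvalue)
            accel = "A" if n_a / (n_a + n_b) > p0 else "B"
        tested.append(
            CategoryRateResult(term, len(members), n_a, n_b, total_a, total_b, p_raw, 1.0, accel)
        )
    if tested:
        adjusted = holm_adjust([r.p_raw for r in tested])
        for r, p in zip(tested, adjusted):
            r.p_holm = float(p)
    return tested


def per_category_rates(
    term_to_genes: dict[str, list[str]],
    alignments: list[CodonAlignment],
    tree: PhyloTree,
    focal_taxa: tuple[str, str] = ("vlangalii", "przewalskii"),
    min_orthologs: int = MIN_CATEGORY_ORTHOLOGS,
) -> dict[str, dict[str, LineageRateSummary]]:
    """Per-category lineage Ka/Ks from per-category concatenations.

    For every term with enough analysed member genes, the member
    alignments are concatenated and fitted with the free-ratio model; the
    two focal lineages' summaries give the category's point in a
    Ka/Ks-vs-Ka/Ks scatter.  This is an expensive whole-category refit and
    is therefore not part of the default pipeline run.
    """
    by_id = {a.gene_id: a for a in alignments}
    out: dict[str, dict[str, LineageRateSummary]] = {}
    for term in sorted(term_to_genes):
        members = [by_id[g] for g in term_to_genes[term] if g in by_id]
        if len(members) < min_orthologs:
            continue
        out[term] = concatenate_and_fit(members, tree, focal_taxa=focal_taxa)
    return out


def write_category_scatter_tsv(
    category_rates: dict[str, dict[str, LineageRateSummary]], path
) -> None:
    """TSV of per-category lineage Ka/Ks pairs (one row per term)."""
    taxa = sorted({t for summaries in category_rates.values() for t in summaries})
    with open(path, "w") as fh:
        fh.write("term_id\t" + "\t".join(f"ka_ks_{t}" for t in taxa) + "\n")
        for term in sorted(category_rates):
            vals = [f"{category_rates[term][t].mean_ka_ks:.4f}" for t in taxa]
            fh.write(term + "\t" + "\t".join(vals) + "\n")


def write_category_tsv(results: list[CategoryRateResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tn_genes\tnA\tnB\tp_raw\tp_holm\taccelerated_lineage\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.n_genes}\t{r.n_a}\t{r.n_b}\t{r.p_raw:.6g}\t{r.p_holm:.6g}\t"
                f"{r.accelerated or 'NA'}\n"
            )
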