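"""Lineage rate summaries, binomial category test, Holm adjustment."""

from math import comb

import numpy as np
import pytest

from codonscan import rates, simulate
from codonscan.models.fit import BranchRates
from codonscan.trees import PhyloTree
from conftest import one_class_model


def _br(gene, n_hat):
    return BranchRates(gene, 0.1, 0.3, 0.01, 0.03, n_hat, n_hat * 3)


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

def test_holm_single_and_all_ones():
    assert rates.holm_adjust([0.2]) == pytest.approx([0.2])
    assert rates.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])


def test_holm_closed_form_example():
    assert rates.holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])


def test_holm_matches_stepdown_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 12))
        got = rates.holm_adjust(p)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            adj[idx] = running
        assert got == pytest.approx(adj)


def test_holm_rejects_invalid():
    with pytest.raises(ValueError):
        rates.holm_adjust([0.2, 1.4])


# ---------------------------------------------------------------------------
# binomial category test
# ---------------------------------------------------------------------------

def _binom_two_sided_oracle(k, n, p):
    pmf = [comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    return sum(q for q in pmf if q <= pmf[k] * (1 + 1e-9))


def test_symmetric_counts_give_p_one():
    term = {"T": [f"g{i}" for i in range(25)]}
    ra = {f"g{i}": _br(f"g{i}", 1.0) for i in range(25)}
    res = rates.category_rate_test(term, ra, ra)
    assert res[0].p_raw == pytest.approx(1.0)
    assert res[0].n_a == res[0].n_b


def test_binomial_p_matches_enumeration():
    genes = [f"g{i}" for i in range(30)]
    term = {"T": genes[:21]}
    ra = {g: _br(g, 1.0 if i < 15 else 0.0) for i, g in enumerate(genes[:21])}
    rb = {g: _br(g, 1.0 if i >= 15 else 0.25) for i, g in enumerate(genes[:21])}
    # include extra genes so the genome-wide totals differ from the term's
    for g in genes[21:]:
        ra[g] = _br(g, 2.0)
        rb[g] = _br(g, 2.0)
    res = rates.category_rate_test(term, ra, rb)
    r = res[0]
    p0 = r.total_a / (r.total_a + r.total_b)
    assert r.p_raw == pytest.approx(_binom_two_sided_oracle(r.n_a, r.n_a + r.n_b, p0), rel=1e-9)


def test_category_needs_more_than_20_orthologs():
    ra = {f"g{i}": _br(f"g{i}", 1.0) for i in range(40)}
    terms = {"T20": [f"g{i}" for i in range(20)], "T21": [f"g{i}" for i in range(21)]}
    res = rates.category_rate_test(terms, ra, ra)
    assert [r.term_id for r in res] == ["T21"]


def test_zero_counts_no_call():
    term = {"T": [f"g{i}" for i in range(25)]}
    ra = {f"g{i}": _br(f"g{i}", 0.0) for i in range(25)}
    res = rates.category_rate_test(term, ra, ra)
    assert res[0].p_raw == 1.0 and res[0].accelerated is None


def test_lineage_swap_symmetry():
    rng = np.random.default_rng(3)
    genes = [f"g{i}" for i in range(60)]
    ra = {g: _br(g, float(rng.poisson(3))) for g in genes}
    rb = {g: _br(g, float(rng.poisson(2))) for g in genes}
    terms = {"T1": genes[:25], "T2": genes[25:55]}
    fwd = rates.category_rate_test(terms, ra, rb)
    rev = rates.category_rate_test(terms, rb, ra)
    for f, r in zip(fwd, rev):
        assert f.p_raw == pytest.approx(r.p_raw, rel=1e-9)
        assert (f.n_a, f.n_b) == (r.n_b, r.n_a)
        if f.accelerated is not None:
            assert {f.accelerated, r.accelerated} == {"A", "B"}


def test_totals_conserved_within_terms():
    genes = [f"g{i}" for i in range(30)]
    ra = {g: _br(g, 1.5) for g in genes}
    terms = {"T": genes[:25]}
    res = rates.category_rate_test(terms, ra, ra)
    assert res[0].n_a == round(1.5 * 25)


def test_familywise_error_controlled_under_null():
    """200 null categories: Holm keeps the familywise rejection rate at bay."""
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(400)]
    ra = {g: _br(g, float(rng.poisson(2.0))) for g in genes}
    rb = {g: _br(g, float(rng.poisson(2.0))) for g in genes}
    terms = {f"T{k}": list(rng.choice(genes, size=25, replace=False)) for k in range(200)}
    res = rates.category_rate_test(terms, ra, rb)
    frac = np.mean([r.p_holm < 0.05 for r in res])
    assert frac <= 0.05


def test_concatenation_of_gene_with_itself_matches_single(default_tree, equal_params):
    aln = simulate.simulate_codon_alignment(
        default_tree, one_class_model(equal_params, 0.3), 200, seed=17, gene_id="g"
    )
    single = rates.concatenate_and_fit([aln], default_tree)
    double = rates.concatenate_and_fit([aln, aln], default_tree)
    for taxon in single:
        assert single[taxon].mean_ka_ks == pytest.approx(double[taxon].mean_ka_ks, abs=0.02)
        assert single[taxon].mean_ka == pytest.approx(double[taxon].mean_ka, abs=0.01)


def test_concatenate_rejects_mismatched_taxa(default_tree, equal_params):
    from codonscan.alignment import CodonAlignment

    a = simulate.simulate_codon_alignment(default_tree, one_class_model(equal_params, 0.3), 80, seed=1, gene_id="a")
    b = CodonAlignment(["x", "y"], ["GCTGCT", "GCTGCT"], gene_id="weird")
    with pytest.raises(ValueError, match="weird"):
        rates.concatenate_and_fit([a, b], default_tree)


def test_per_category_scatter_from_concatenations(tmp_path, default_tree, equal_params):
    alns = [
        simulate.simulate_codon_alignment(
            default_tree, one_class_model(equal_params, 0.3), 80, seed=200 + k, gene_id=f"g{k}")
        for k in range(4)
    ]
    terms = {"T1": ["g0", "g1", "g2"], "Tsmall": ["g3"]}
    cat = rates.per_category_rates(terms, alns, default_tree, min_orthologs=3)
    assert list(cat) == ["T1"]  # the 1-gene term is below the ortholog floor
    assert set(cat["T1"]) == {"vlangalii", "przewalskii"}
    out = tmp_path / "scatter.tsv"
    rates.write_category_scatter_tsv(cat, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "term_id\tka_ks_przewalskii\tka_ks_vlangalii"
    assert lines[1].startswith("T1\t")
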