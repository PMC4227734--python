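"""Consensus calling, block trimming, filters, saturation screen."""

import itertools

import numpy as np
import pytest

from codonscan import qc, simulate
from codonscan.alignment import CodonAlignment
from codonscan.trees import PhyloTree
from conftest import one_class_model


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_majority_zero_and_tie():
    assert qc.consensus_call([{"A": 10, "G": 3}]) == "A"
    assert qc.consensus_call([{"A": 0, "C": 0, "G": 0, "T": 0}]) == "N"
    assert qc.consensus_call([{"A": 5, "T": 5}]) == "A"


def test_consensus_tie_rule_full_enumeration():
    """Every tie pattern resolves to the alphabetically first tied base."""
    for pattern in itertools.product([0, 3], repeat=4):
        if sum(pattern) == 0:
            expected = "N"
        else:
            expected = "ACGT"[pattern.index(3)]
        counts = dict(zip("ACGT", pattern))
        assert qc.consensus_call([counts]) == expected


def test_consensus_rejects_negative_counts():
    with pytest.raises(ValueError):
        qc.consensus_call([{"A": -1}])


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _conserved_block(n_codons, taxa=5):
    return ["ATGGCTAAA"[0:3] * n_codons] * taxa


def test_trim_conserved_alignment_unchanged():
    aln = CodonAlignment(list("abcde"), ["ATGGCTAAAGCTGCT" * 2] * 5)
    out = qc.trim_alignment_blocks(aln)
    assert out.sequences == aln.sequences


def test_trim_gap_columns_excluded_and_blocks_enforced():
    """30 conserved + 4 gap-riddled + 30 conserved codons -> 60 codons."""
    good = "ATG" * 30
    bad = "---" * 4
    seqs = []
    for i in range(5):
        middle = bad if i < 3 else "GCT" * 4  # 3/5 taxa gapped in the middle
        seqs.append(good + middle + good)
    aln = CodonAlignment(list("abcde"), seqs)
    out = qc.trim_alignment_blocks(aln, min_block=5, max_gap_fraction=0.0)
    assert out.n_codons == 60


def test_trim_short_runs_dropped():
    good = "ATG" * 3  # below min_block
    bad = "---" * 2
    seqs = [bad + good + bad if i == 0 else "GCT" * 2 + good + "GCT" * 2 for i in range(5)]
    aln = CodonAlignment(list("abcde"), seqs)
    out = qc.trim_alignment_blocks(aln, min_block=5, max_gap_fraction=0.0)
    assert out.n_codons == 0


def test_trim_idempotent(default_tree, equal_params):
    aln = simulate.simulate_codon_alignment(default_tree, one_class_model(equal_params, 0.3), 80, seed=5)
    once = qc.trim_alignment_blocks(aln)
    twice = qc.trim_alignment_blocks(once)
    assert once.sequences == twice.sequences


# ---------------------------------------------------------------------------
# stop/length filter
# ---------------------------------------------------------------------------

def test_length_boundary_at_200_bp():
    taxa = list("abcde")
    short = CodonAlignment(taxa, ["GCT" * 66] * 5, gene_id="short")   # 198 bp
    keep = CodonAlignment(taxa, ["GCT" * 67] * 5, gene_id="keep")     # 201 bp
    kept, rejected = qc.filter_orthologs([short, keep])
    assert [a.gene_id for a in kept] == ["keep"]
    assert rejected[0][0] == "short"


def test_internal_stop_discarded():
    taxa = list("abcde")
    seqs = ["GCT" * 30 + "TAA" + "GCT" * 40] * 5
    aln = CodonAlignment(taxa, seqs, gene_id="stopgene")
    kept, rejected = qc.filter_orthologs([aln])
    assert kept == []
    assert "stop" in rejected[0][1]


def test_clean_long_gene_kept_and_filter_idempotent():
    aln = CodonAlignment(list("abcde"), ["GCT" * 300] * 5, gene_id="clean")
    kept, _ = qc.filter_orthologs([aln])
    kept2, rejected2 = qc.filter_orthologs(kept)
    assert [a.gene_id for a in kept2] == ["clean"]
    assert rejected2 == []


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def test_identical_sequences_not_saturated(default_tree):
    aln = CodonAlignment(list(default_tree.leaf_labels), ["GCTAAAGGT" * 30] * 5)
    verdict = qc.saturation_test(aln, default_tree)
    assert not verdict.saturated
    assert verdict.max_branch_length < 0.01


def test_gtr_pruning_matches_brute_force():
    """4 taxa x 3 sites: pruning equals summation over internal states."""
    import scipy.linalg
    from codonscan.models.likelihood import compress_patterns, site_likelihoods
    from codonscan.models import matrices

    tree = PhyloTree.from_newick("((a:0.2,b:0.3):0.15,c:0.4,d:0.25);")
    pi = np.array([0.3, 0.2, 0.2, 0.3])
    ex = np.array([1.0, 2.0, 0.7, 1.1, 2.4, 1.0])
    Q = matrices.gtr_rate_matrix(ex, pi)
    seqs = {"a": "ACG", "b": "ACT", "c": "GCT", "d": "ACT"}
    mat = qc._encode_nt([seqs[t] for t in "abcd"])
    patterns, weights = compress_patterns(mat)
    leaf_rows = {leaf: "abcd".index(tree.labels[leaf]) for leaf in tree.leaves}
    lengths = {e: float(tree.lengths[e]) for e in tree.edges}
    P_by_edge = {e: scipy.linalg.expm(Q * lengths[e]) for e in tree.edges}
    L = site_likelihoods(tree, P_by_edge, patterns, leaf_rows, pi)
    lnl = float(weights @ np.log(L))

    Ps = {lbl: scipy.linalg.expm(Q * t) for lbl, t in
          [("a", 0.2), ("b", 0.3), ("ab", 0.15), ("c", 0.4), ("d", 0.25)]}
    nt = {b: i for i, b in enumerate("ACGT")}
    brute = 0.0
    for site in range(3):
        a, b, c, d = (nt[seqs[x][site]] for x in "abcd")
        lik = 0.0
        for r in range(4):
            inner = sum(Ps["ab"][r, u] * Ps["a"][u, a] * Ps["b"][u, b] for u in range(4))
            lik += pi[r] * inner * Ps["c"][r, c] * Ps["d"][r, d]
        brute += np.log(lik)
    assert abs(lnl - brute) / abs(brute) < 1e-10


def test_gtr_branch_length_recovery(default_tree):
    """Mean estimates across replicates recover t in {0.05, 0.2, 0.5} within 15%."""
    ex = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
    pi = np.array([0.3, 0.2, 0.2, 0.3])
    for true_t, base_seed in [(0.05, 10), (0.2, 20), (0.5, 30)]:
        sim_tree = default_tree.with_lengths(np.full(7, true_t))
        ests = []
        for rep in range(3):
            seqs = simulate.simulate_nucleotide_alignment(sim_tree, ex, pi, 2000, base_seed + rep)
            fitted = qc.fit_gtr_branch_lengths(seqs, default_tree)
            ests.append(np.mean(list(fitted.lengths.values())))
        assert abs(np.mean(ests) - true_t) / true_t < 0.15


def test_random_third_positions_saturated(default_tree):
    rng = np.random.default_rng(0)
    taxa = list(default_tree.leaf_labels)
    seqs = []
    for _ in taxa:
        third = rng.integers(0, 4, size=150)
        seqs.append("".join("GC" + "ACGT"[i] for i in third))
    aln = CodonAlignment(taxa, seqs)
    verdict = qc.saturation_test(aln, default_tree)
    assert verdict.saturated
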