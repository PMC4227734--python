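"""Translated similarity search and best-reciprocal-hit calling."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from codonscan import orthology
from codonscan.genetics import SENSE_CODONS


@pytest.fixture(scope="module")
def search():
    return orthology.TranslatedSearch()


def _rand_cds(n, rng):
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, size=n))


def test_identity_hit(search):
    rng = np.random.default_rng(1)
    cds = _rand_cds(50, rng)
    hit = orthology.translated_similarity(cds, cds, search=search)
    assert hit.query_frame == 1 and hit.target_frame == 1
    assert hit.query_span == (0, len(cds))
    # score equals the peptide self-alignment score under BLOSUM62
    blosum = substitution_matrices.load("BLOSUM62")
    pep = str(Seq(cds).translate())
    assert hit.score == pytest.approx(sum(blosum[a, a] for a in pep))


def test_reverse_complement_same_score_negative_frame(search):
    rng = np.random.default_rng(2)
    cds = _rand_cds(40, rng)
    rc = str(Seq(cds).reverse_complement())
    fwd = orthology.translated_similarity(cds, cds, search=search)
    rev = orthology.translated_similarity(rc, cds, search=search)
    assert rev.score == fwd.score
    assert rev.query_frame < 0
    assert rev.query_span == (0, len(cds))


def test_score_matches_affine_gap_dp_oracle(search):
    """Exhaustive Gotoh local alignment on the translated peptides."""
    rng = np.random.default_rng(3)
    cds_a = _rand_cds(30, rng)
    # mutate 3 amino acids
    codons = [cds_a[i:i + 3] for i in range(0, 90, 3)]
    for pos in (5, 12, 21):
        codons[pos] = SENSE_CODONS[int(rng.integers(0, 61))]
    cds_b = "".join(codons)

    pep_a = str(Seq(cds_a).translate())
    pep_b = str(Seq(cds_b).translate())
    blosum = substitution_matrices.load("BLOSUM62")

    def gotoh_local(x, y, open_=11.0, extend=1.0):
        n, m = len(x), len(y)
        M = np.zeros((n + 1, m + 1))
        Ix = np.full((n + 1, m + 1), -np.inf)
        Iy = np.full((n + 1, m + 1), -np.inf)
        best = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - extend)
                Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - extend)
                s = blosum[x[i - 1], y[j - 1]]
                M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]))
                best = max(best, M[i, j], Ix[i, j], Iy[i, j])
        return best

    hit = orthology.translated_similarity(cds_a, cds_b, search=search)
    assert hit.score == pytest.approx(gotoh_local(pep_a, pep_b))


def test_empty_and_all_n_sequences(search):
    with pytest.raises(ValueError):
        orthology.translated_similarity("", "ATGGCT", search=search)
    hit = orthology.translated_similarity("NNNNNNNNN", "ATGGCTAAA", search=search)
    assert hit.score <= 0.0 or np.isfinite(hit.score)


def test_reciprocity_required(search):
    rng = np.random.default_rng(5)
    cds = _rand_cds(60, rng)
    # t1 is an exact copy; t2 is a slightly mutated copy that still prefers cds,
    # but cds prefers t1 -> t2 must not be paired
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    codons[4] = "TGG" if codons[4] != "TGG" else "TGT"
    t2 = "".join(codons)
    pairs, _ = orthology.best_reciprocal_hits(
        {"t1": cds, "t2": t2}, {"c": cds}, min_score=50, search=search)
    assert [(p.transcript_id, p.cds_id) for p in pairs] == [("t1", "c")]


def test_exact_copy_is_paired(search):
    rng = np.random.default_rng(6)
    cds_set = {f"c{i}": _rand_cds(50, rng) for i in range(3)}
    pairs, _ = orthology.best_reciprocal_hits(
        {"t": cds_set["c1"]}, cds_set, min_score=50, search=search)
    assert [(p.transcript_id, p.cds_id) for p in pairs] == [("t", "c1")]


def test_output_is_partial_matching_and_min_score_monotone(search):
    rng = np.random.default_rng(7)
    from codonscan import simulate
    cds = {f"g{i}": _rand_cds(60, rng) for i in range(6)}
    transcripts, _ = simulate.make_transcript_decoys(cds, seed=2, n_random=2)
    lo, _ = orthology.best_reciprocal_hits(transcripts, cds, min_score=40, search=search)
    hi, _ = orthology.best_reciprocal_hits(transcripts, cds, min_score=120, search=search)
    for pairs in (lo, hi):
        assert len({p.transcript_id for p in pairs}) == len(pairs)
        assert len({p.cds_id for p in pairs}) == len(pairs)
    assert {(p.transcript_id, p.cds_id) for p in hi} <= {(p.transcript_id, p.cds_id) for p in lo}


def test_calibrated_threshold_separates_homologs(search):
    rng = np.random.default_rng(8)
    cds = {f"g{i}": _rand_cds(60, rng) for i in range(4)}
    thr = orthology.calibrate_min_score(cds, cds, n_shuffles=50, quantile=0.98, seed=0, search=search)
    # genuine self-hits score far above the shuffled null
    self_score = search.score(cds["g0"], cds["g0"])
    assert self_score > thr > 0


def test_brh_recovers_orthologs_across_fifty_families(search):
    """Orthologs ~95% identity, paralogs ~60%: >= 95% of true pairs recovered."""
    rng = np.random.default_rng(50)
    from codonscan import simulate

    cds = {f"g{i:03d}": _rand_cds(80, rng) for i in range(50)}
    transcripts, manifest = simulate.make_transcript_decoys(cds, seed=50, fragmentation=0.0)
    pairs, _ = orthology.best_reciprocal_hits(transcripts, cds, min_score=60, search=search)
    labels = manifest.labels()
    true_hits = sum(
        1 for p in pairs
        if labels[p.transcript_id] == "ortholog" and p.transcript_id == f"{p.cds_id}_transcript"
    )
    assert true_hits / 50 >= 0.95
    # paralogs and random sequence must not displace the true orthologs
    assert all(labels[p.transcript_id] == "ortholog" for p in pairs)
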