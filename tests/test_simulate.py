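"""Simulator contracts: determinism, degenerate settings, statistical fidelity."""

import numpy as np
import pytest
from scipy import stats

from codonscan import genetics, simulate
from codonscan.models import fit, matrices
from codonscan.trees import PhyloTree
from conftest import one_class_model


def test_same_seed_bitwise_identical(default_tree, equal_params):
    model = one_class_model(equal_params, 0.5)
    a1 = simulate.simulate_codon_alignment(default_tree, model, 100, seed=3)
    a2 = simulate.simulate_codon_alignment(default_tree, model, 100, seed=3)
    assert a1.sequences == a2.sequences


def test_zero_branch_lengths_copy_root(equal_params):
    tree = PhyloTree.from_newick("((a:0,b:0):0,c:0,d:0);")
    model = one_class_model(equal_params, 0.5)
    aln = simulate.simulate_codon_alignment(tree, model, 50, seed=1)
    assert len(set(aln.sequences)) == 1


def test_omega_zero_preserves_amino_acids(default_tree, equal_params):
    model = one_class_model(equal_params, 0.0)
    aln = simulate.simulate_codon_alignment(default_tree, model, 200, seed=2)
    peptides = {genetics.translate(s) for s in aln.sequences}
    assert len(peptides) == 1


def test_counting_estimate_near_one_at_neutral(pair_tree, equal_params):
    """t=0.5, omega=1, kappa=2, 20k codons: counting dN/dS within 0.1 of 1."""
    from codonscan.models.ng86 import ng86_pairwise

    model = one_class_model(equal_params, 1.0)
    aln = simulate.simulate_codon_alignment(pair_tree, model, 20000, seed=2)
    r = ng86_pairwise(aln.sequences[0], aln.sequences[1], kappa=2.0)
    assert abs(r.ratio - 1.0) < 0.1


def test_negative_branch_length_rejected(equal_params):
    tree = PhyloTree.default()
    tree.lengths[1] = -0.1
    with pytest.raises(ValueError):
        simulate.simulate_codon_alignment(tree, one_class_model(equal_params, 1.0), 10, seed=0)


def test_stationary_frequencies_converge(equal_params):
    """Empirical codon frequencies at a leaf match pi (chi-square, alpha=0.01)."""
    pair = PhyloTree.from_newick("(a:0.5,b:0.1);")
    model = one_class_model(equal_params, 1.0)
    aln = simulate.simulate_codon_alignment(pair, model, 100_000, seed=13)
    states = genetics.encode_codons(aln.sequences[0])
    counts = np.bincount(states, minlength=61)
    chi2, p = stats.chisquare(counts, equal_params.pi * counts.sum())
    assert p > 0.01


def test_substitution_count_scales_linearly_with_t(equal_params):
    """ML branch-length estimates regress on true t with slope within 5%."""
    ts = np.array([0.05, 0.2, 0.4, 0.7, 1.0])
    est = []
    model = one_class_model(equal_params, 1.0)
    for k, t in enumerate(ts):
        pair = PhyloTree.from_newick(f"(a:{t},b:0.0);")
        aln = simulate.simulate_codon_alignment(pair, model, 4000, seed=100 + k)
        est.append(fit.fit_free_ratio(aln, pair, pi=equal_params.pi)["a--b"].t)
    slope = np.polyfit(ts, est, 1)[0]
    assert abs(slope - 1.0) < 0.05


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def test_psg_quota_is_exact():
    cfg = simulate.SimulationConfig(n_genes=100, psg_fraction=0.2, n_codons_range=(10, 12),
                                    n_terms=5, term_size_range=(5, 10), seed=7)
    study = simulate.generate_ortholog_study(cfg)
    assert len(study.true_psgs()) == 20
    assert len(study.alignments) == 100
    assert study.truth["gene_id"].is_unique


def test_psg_fraction_zero_and_empty_study(tmp_path):
    cfg = simulate.SimulationConfig(n_genes=10, psg_fraction=0.0, n_codons_range=(10, 12),
                                    n_terms=3, term_size_range=(3, 5), n_enriched_terms=0, seed=1)
    study = simulate.generate_ortholog_study(cfg)
    assert study.true_psgs() == set()
    empty = simulate.generate_ortholog_study(
        simulate.SimulationConfig(n_genes=0, n_codons_range=(10, 12), n_terms=0, seed=1),
        run_dir=tmp_path / "empty",
    )
    assert empty.alignments == []
    assert (tmp_path / "empty" / "manifest.json").exists()


def test_identical_seeds_give_byte_identical_files(tmp_path):
    cfg = dict(n_genes=5, psg_fraction=0.4, n_codons_range=(10, 15), n_terms=4,
               term_size_range=(2, 4), seed=42)
    for d in ("r1", "r2"):
        simulate.generate_ortholog_study(simulate.SimulationConfig(**cfg), run_dir=tmp_path / d)
    for rel in ["annotations.tsv", "truth.tsv", "manifest.json", "families/g00000.fasta"]:
        assert (tmp_path / "r1" / rel).read_bytes() == (tmp_path / "r2" / rel).read_bytes()


def test_every_gene_annotated():
    cfg = simulate.SimulationConfig(n_genes=50, n_codons_range=(10, 12), n_terms=6,
                                    term_size_range=(5, 10), seed=3)
    study = simulate.generate_ortholog_study(cfg)
    annotated = {g for members in study.annotations.values() for g in members}
    assert annotated == set(study.gene_ids)


def test_config_validation():
    with pytest.raises(ValueError):
        simulate.SimulationConfig(psg_fraction=1.5)
    with pytest.raises(ValueError):
        simulate.SimulationConfig(kappa=-1.0)
    freqs = np.zeros(64)
    freqs[:10] = 0.1
    freqs[genetics.ALL_CODONS.index("TAA")] = 0.05  # stop codon support
    with pytest.raises(ValueError, match="stop"):
        simulate.SimulationConfig(codon_frequencies=freqs / freqs.sum()).pi()


def test_decoy_manifest_partitions_output():
    rng = np.random.default_rng(4)
    cds = {f"g{i}": "".join(genetics.SENSE_CODONS[j] for j in rng.integers(0, 61, 60))
           for i in range(5)}
    transcripts, manifest = simulate.make_transcript_decoys(cds, seed=1)
    labels = manifest.labels()
    assert set(labels) == set(transcripts)
    assert set(labels.values()) == {"ortholog", "paralog", "random"}


def test_decoy_zero_divergence_equals_source():
    cds = {"g": "ATGGCTGCTAAAGGTTTGACTGAAGCTCAT"}
    transcripts, manifest = simulate.make_transcript_decoys(
        cds, paralog_divergence=0.0, ortholog_divergence=0.0, fragmentation=0.0,
        flank_range=(0, 0), seed=0, n_random=0,
    )
    assert transcripts["g_paralog"] == cds["g"]
    assert transcripts["g_transcript"] == cds["g"]


def test_decoy_fragmentation_validated():
    with pytest.raises(ValueError):
        simulate.make_transcript_decoys({"g": "ATGGCT"}, fragmentation=1.5)
    with pytest.raises(ValueError):
        simulate.make_transcript_decoys({}, fragmentation=0.0)
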