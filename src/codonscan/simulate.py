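"""Synthetic ortholog studies with known truth.

Codon alignments are simulated forward along the species tree under the
same continuous-time codon process the inference side fits: root states are
drawn from the stationary codon frequencies and evolved through
``P(t) = exp(Qt)`` branch by branch, with per-site branch-site class
assignments (classes 0, 1, 2a, 2b under the constraint
``p2a : p2b = p0 : p1``).  A configurable fraction of genes carries a
foreground ``omega2 > 1`` regime; the rest are simulated with
``omega2 = 1``.  The generator also emits decoy transcripts (diverged
paralog copies, truncated orthologs with untranslated flanks, unrelated
random sequence) for orthology testing, and a randomised gene-to-term
annotation table with a configurable number of truly PSG-enriched terms.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetics
from .alignment import CodonAlignment
from .models import matrices
from .models.likelihood import SiteClassModel
from .trees import PhyloTree


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_states(P: np.ndarray, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states given parent states and a row-stochastic P."""
    if states.size == 0:
        return states.copy()
    cum = P.cumsum(axis=1)[states]
    u = rng.random(states.size)
    child = (cum < u[:, None]).sum(axis=1)
    return np.minimum(child, P.shape[0] - 1)


def simulate_codon_alignment(
    tree: PhyloTree,
    model: SiteClassModel,
    n_codons: int,
    seed,
    gene_id: str = "",
    return_classes: bool = False,
):
    """Simulate one aligned codon family on ``tree`` under ``model``.

    Returns a :class:`CodonAlignment` (and, optionally, the per-site class
    assignment array).  All branch lengths zero reproduces the root draw at
    every leaf; ``omega = 0`` everywhere forbids amino-acid change.
    """
    if np.any(tree.lengths < 0):
        raise ValueError("negative branch length")
    rng = _as_rng(seed)
    params = model.params
    weights = np.array([w for w, _, _ in model.classes])
    classes = rng.choice(len(model.classes), size=n_codons, p=weights / weights.sum())
    states = {0: rng.choice(genetics.N_SENSE, size=n_codons, p=params.pi)}
    spectral: dict[float, matrices.SpectralMatrix] = {}

    def spec_for(omega: float) -> matrices.SpectralMatrix:
        if omega not in spectral:
            spectral[omega] = matrices.codon_spectral(params, omega)
        return spectral[omega]

    order = [n for n in reversed(tree.postorder) if n != 0]  # preorder, skip root
    for node in order:
        parent_states = states[tree.parent[node]]
        child = np.empty(n_codons, dtype=np.int64)
        t = float(tree.lengths[node])
        for c, (_, omega_bg, omega_fg) in enumerate(model.classes):
            omega = omega_fg if node == tree.foreground else omega_bg
            idx = np.flatnonzero(classes == c)
            if t == 0.0:
                child[idx] = parent_states[idx]
            else:
                # branch lengths are neutral-scale: an omega class runs at
                # relative rate g(omega) = omega * a + b
                g = matrices.relative_rate(params, omega)
                P = spec_for(omega).transition_matrix(g * t)
                child[idx] = _sample_states(P, parent_states[idx], rng)
        states[node] = child

    taxa = [tree.labels[leaf] for leaf in tree.leaves]
    seqs = [genetics.decode_codons(states[leaf]) for leaf in tree.leaves]
    aln = CodonAlignment(taxa, seqs, gene_id=gene_id)
    return (aln, classes) if return_classes else aln


def simulate_nucleotide_alignment(
    tree: PhyloTree,
    exchangeabilities: np.ndarray,
    pi: np.ndarray,
    n_sites: int,
    seed,
) -> dict[str, str]:
    """Simulate nucleotide sequences under GTR; returns label -> sequence."""
    if np.any(tree.lengths < 0):
        raise ValueError("negative branch length")
    rng = _as_rng(seed)
    spec = matrices.gtr_spectral(exchangeabilities, pi)
    states = {0: rng.choice(4, size=n_sites, p=np.asarray(pi, dtype=float))}
    for node in [n for n in reversed(tree.postorder) if n != 0]:
        t = float(tree.lengths[node])
        parent_states = states[tree.parent[node]]
        if t == 0.0:
            states[node] = parent_states.copy()
        else:
            states[node] = _sample_states(spec.transition_matrix(t), parent_states, rng)
    return {
        tree.labels[leaf]: "".join(genetics.NUCLEOTIDES[s] for s in states[leaf])
        for leaf in tree.leaves
    }


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for a synthetic ortholog dataset."""

    tree: PhyloTree = None
    n_genes: int = 200
    n_codons_range: tuple[int, int] = (200, 300)
    kappa: float = 2.0
    background_omega: float = 0.2
    psg_fraction: float = 0.2
    foreground_omega2: float = 5.0
    p0: float = 0.45
    p1: float = 0.30
    codon_frequencies: str | np.ndarray = "equal"
    paralog_divergence: float = 2.0
    n_terms: int = 40
    term_size_range: tuple[int, int] = (25, 40)
    n_enriched_terms: int = 3
    enriched_psg_share: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.tree is None:
            self.tree = PhyloTree.default()
        if not 0.0 <= self.psg_fraction <= 1.0:
            raise ValueError("psg_fraction must be in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.background_omega < 0:
            raise ValueError("background_omega must be >= 0")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1:
            raise ValueError("site-class proportions p0, p1 must be >= 0 with p0 + p1 <= 1")

    def pi(self) -> np.ndarray:
        if isinstance(self.codon_frequencies, str):
            if self.codon_frequencies != "equal":
                raise ValueError(f"unknown frequency mode {self.codon_frequencies!r}")
            return genetics.equal_codon_frequencies()
        freqs = np.asarray(self.codon_frequencies, dtype=float)
        if freqs.shape == (64,):
            stops = [genetics.ALL_CODONS.index(s) for s in genetics.STOP_CODONS]
            if np.any(freqs[stops] > 0):
                raise ValueError("stop codons must carry zero frequency")
            freqs = np.delete(freqs, stops)
        if freqs.shape != (genetics.N_SENSE,):
            raise ValueError("codon frequencies must cover the 61 sense codons")
        if np.any(freqs < 0) or not np.isclose(freqs.sum(), 1.0, atol=1e-8):
            raise ValueError("codon frequencies must sum to 1")
        return freqs / freqs.sum()

    def site_class_model(self, omega2: float) -> SiteClassModel:
        p2 = 1.0 - self.p0 - self.p1
        tot = self.p0 + self.p1
        p2a = p2 * self.p0 / tot if tot > 0 else 0.0
        p2b = p2 * self.p1 / tot if tot > 0 else 0.0
        w0 = self.background_omega
        params = matrices.CodonModelParams(self.kappa, self.pi())
        return SiteClassModel(
            params,
            [(self.p0, w0, w0), (self.p1, 1.0, 1.0), (p2a, w0, omega2), (p2b, 1.0, omega2)],
        )


@dataclass
class OrthologStudy:
    config: SimulationConfig
    alignments: list[CodonAlignment]
    truth: pd.DataFrame
    annotations: dict[str, list[str]]  # term -> gene ids
    enriched_terms: list[str]
    run_dir: Path | None = None

    @property
    def gene_ids(self) -> list[str]:
        return [a.gene_id for a in self.alignments]

    def true_psgs(self) -> set[str]:
        return set(self.truth.loc[self.truth["regime"] == "selected", "gene_id"])


def generate_ortholog_study(config: SimulationConfig, run_dir: str | Path | None = None) -> OrthologStudy:
    """Simulate a full ortholog study: families, annotations and truth table.

    The positively selected genes are a deterministic quota: the first
    ``floor(psg_fraction * n_genes)`` indices of a seeded permutation, so
    truth counts are exact.  If ``run_dir`` is given, per-gene FASTA files,
    the annotation TSV, the truth TSV and a manifest JSON are written there.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_selected = int(np.floor(config.psg_fraction * n))
    order = rng.permutation(n)
    selected = np.zeros(n, dtype=bool)
    selected[order[:n_selected]] = True

    gene_ids = [f"g{i:05d}" for i in range(n)]
    alignments: list[CodonAlignment] = []
    records = []
    lo, hi = config.n_codons_range
    for i, gene in enumerate(gene_ids):
        n_codons = int(rng.integers(lo, hi + 1))
        omega2 = config.foreground_omega2 if selected[i] else 1.0
        model = config.site_class_model(omega2)
        aln = simulate_codon_alignment(config.tree, model, n_codons, rng, gene_id=gene)
        alignments.append(aln)
        records.append(
            {
                "gene_id": gene,
                "regime": "selected" if selected[i] else "null",
                "omega0": config.background_omega,
                "omega2": omega2,
                "n_codons": n_codons,
            }
        )
    truth = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["gene_id", "regime", "omega0", "omega2", "n_codons"]
    )

    annotations, enriched_terms = _random_annotations(config, gene_ids, selected, rng)
    terms_of: dict[str, list[str]] = {g: [] for g in gene_ids}
    for term, members in annotations.items():
        for g in members:
            terms_of[g].append(term)
    if not truth.empty:
        truth["terms"] = [",".join(terms_of[g]) for g in truth["gene_id"]]

    study = OrthologStudy(config, alignments, truth, annotations, enriched_terms)
    if run_dir is not None:
        study.run_dir = _write_study(study, Path(run_dir))
    return study


def _random_annotations(config, gene_ids, selected, rng):
    n = len(gene_ids)
    annotations: dict[str, list[str]] = {}
    enriched: list[str] = []
    if n == 0 or config.n_terms == 0:
        return annotations, enriched
    ids = np.asarray(gene_ids)
    sel_ids = ids[selected]
    null_ids = ids[~selected]
    lo, hi = config.term_size_range
    for k in range(config.n_terms):
        term = f"T{k:04d}"
        size = int(rng.integers(lo, min(hi, n) + 1)) if n >= lo else n
        if k < config.n_enriched_terms and sel_ids.size > 0:
            n_sel = min(int(round(config.enriched_psg_share * size)), sel_ids.size)
            n_null = min(size - n_sel, null_ids.size)
            members = np.concatenate(
                [
                    rng.choice(sel_ids, size=n_sel, replace=False),
                    rng.choice(null_ids, size=n_null, replace=False),
                ]
            )
            enriched.append(term)
        else:
            members = rng.choice(ids, size=min(size, n), replace=False)
        annotations[term] = sorted(members.tolist())
    # every gene carries at least one term
    annotated = {g for members in annotations.values() for g in members}
    plain_terms = [t for t in annotations if t not in enriched] or list(annotations)
    for g in gene_ids:
        if g not in annotated:
            term = plain_terms[int(rng.integers(len(plain_terms)))]
            annotations[term] = sorted(annotations[term] + [g])
    return annotations, enriched


def _write_study(study: OrthologStudy, run_dir: Path) -> Path:
    run_dir.mkdir(parents=True, exist_ok=True)
    fam_dir = run_dir / "families"
    fam_dir.mkdir(exist_ok=True)
    for aln in study.alignments:
        aln.to_fasta(fam_dir / f"{aln.gene_id}.fasta")
    rows = [(g, t) for t, members in sorted(study.annotations.items()) for g in members]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).sort_values(
        ["gene_id", "term_id"]
    ).to_csv(run_dir / "annotations.tsv", sep="\t", index=False)
    study.truth.to_csv(run_dir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "n_genes": study.config.n_genes,
        "psg_fraction": study.config.psg_fraction,
        "seed": study.config.seed,
        "tree": study.config.tree.to_newick(),
        "enriched_terms": study.enriched_terms,
        "gene_ids": study.gene_ids,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return run_dir


# ---------------------------------------------------------------------------
# transcript decoys for orthology testing
# ---------------------------------------------------------------------------

@dataclass
class DecoyManifest:
    records: list[dict] = field(default_factory=list)

    def labels(self) -> dict[str, str]:
        return {r["transcript_id"]: r["label"] for r in self.records}


def _evolve_cds(seq: str, divergence: float, params: matrices.CodonModelParams, omega: float, rng) -> str:
    if divergence == 0.0:
        return seq
    states = genetics.encode_codons(seq)
    P = matrices.codon_spectral(params, omega).transition_matrix(divergence)
    out = states.copy()
    ok = states >= 0
    out[ok] = _sample_states(P, states[ok], rng)
    return "".join(
        genetics.SENSE_CODONS[s] if s >= 0 else seq[3 * k : 3 * k + 3] for k, s in enumerate(out)
    )


def _random_nt(length: int, rng) -> str:
    return "".join(genetics.NUCLEOTIDES[i] for i in rng.integers(0, 4, size=length))


def make_transcript_decoys(
    cds_set: dict[str, str],
    paralog_divergence: float = 2.0,
    fragmentation: float = 0.0,
    seed: int = 0,
    ortholog_divergence: float = 0.15,
    flank_range: tuple[int, int] = (30, 120),
    n_random: int | None = None,
    kappa: float = 2.0,
    omega: float = 0.2,
) -> tuple[dict[str, str], DecoyManifest]:
    """Build a transcript set with known ortholog/paralog/random labels.

    For every CDS the set contains a true-ortholog transcript (the CDS
    evolved by ``ortholog_divergence``, optionally truncated, wrapped in
    random untranslated flanks) and a paralog copy evolved by the much
    larger ``paralog_divergence``.  ``fragmentation`` is the probability a
    transcript is truncated to a random 40-90 % codon window; values above 1
    are rejected.  Unrelated random sequences round out the decoys.
    """
    if not cds_set:
        raise ValueError("cds_set must be non-empty")
    if not 0.0 <= fragmentation <= 1.0:
        raise ValueError("fragmentation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    params = matrices.CodonModelParams(kappa, genetics.equal_codon_frequencies())
    transcripts: dict[str, str] = {}
    manifest = DecoyManifest()

    def wrap(core: str) -> str:
        lo, hi = flank_range
        if hi <= 0:
            return core
        left = _random_nt(int(rng.integers(lo, hi + 1)), rng)
        right = _random_nt(int(rng.integers(lo, hi + 1)), rng)
        return left + core + right

    def maybe_truncate(core: str) -> str:
        if fragmentation > 0 and rng.random() < fragmentation:
            n_cod = len(core) // 3
            keep = max(1, int(n_cod * rng.uniform(0.4, 0.9)))
            start = int(rng.integers(0, n_cod - keep + 1))
            return core[3 * start : 3 * (start + keep)]
        return core

    for name, cds in cds_set.items():
        core = maybe_truncate(_evolve_cds(cds, ortholog_divergence, params, omega, rng))
        tid = f"{name}_transcript"
        transcripts[tid] = wrap(core)
        manifest.records.append({"transcript_id": tid, "label": "ortholog", "source_gene": name})

        para = maybe_truncate(_evolve_cds(cds, paralog_divergence, params, omega, rng))
        pid = f"{name}_paralog"
        transcripts[pid] = wrap(para)
        manifest.records.append({"transcript_id": pid, "label": "paralog", "source_gene": name})

    n_rand = n_random if n_random is not None else max(3, len(cds_set) // 5)
    mean_len = int(np.mean([len(s) for s in cds_set.values()]))
    for k in range(n_rand):
        rid = f"random_{k:03d}"
        transcripts[rid] = _random_nt(mean_len, rng)
        manifest.records.append({"transcript_id": rid, "label": "random", "source_gene": None})
    return transcripts, manifest
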