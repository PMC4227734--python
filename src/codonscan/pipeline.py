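"""End-to-end positive-selection scan and the Sanger-concordance utility.

``run_pipeline`` chains the stages — simulate (optional), ortholog
determination (optional), alignment QC with the saturation screen, the
branch-site scan, free-ratio lineage rates with category acceleration
tests, and PSG over-representation — writing one TSV/JSON per stage under
a run directory plus a machine-readable summary.  Re-running with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import yaml
from Bio.Align import PairwiseAligner

from . import enrichment as enrich_mod
from . import qc as qc_mod
from . import rates as rates_mod
from .alignment import CodonAlignment
from .models.fit import fit_branch_site, fit_free_ratio, fit_two_ratio
from .models.likelihood import LikelihoodEngine
from .simulate import OrthologStudy, SimulationConfig, generate_ortholog_study
from .trees import PhyloTree, DEFAULT_NEWICK

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds and stage toggles; defaults are the scan's canon."""

    outdir: str = "codonscan_run"
    tree_newick: str = DEFAULT_NEWICK
    foreground_taxon: str = "vlangalii"
    focal_taxa: tuple[str, str] = ("vlangalii", "przewalskii")
    psg_alpha: float = 0.05
    saturation_threshold: float = 1.0
    min_len_bp: int = 200
    min_category_orthologs: int = 21
    es_threshold: float = 1.3
    seed: int = 0
    # stage toggles
    run_qc: bool = True
    run_scan: bool = True
    run_rates: bool = True
    run_enrich: bool = True
    # simulation stage (used when no input alignments are supplied)
    simulation: SimulationConfig | None = None

    def __post_init__(self):
        for name in ("psg_alpha", "saturation_threshold", "min_len_bp", "min_category_orthologs", "es_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        tree = self.tree()
        if self.foreground_taxon not in tree.leaf_labels:
            raise ValueError(f"foreground taxon {self.foreground_taxon!r} not in tree")

    def tree(self) -> PhyloTree:
        return PhyloTree.from_newick(self.tree_newick, foreground_taxon=self.foreground_taxon)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = data.pop("simulation", None)
        cfg = cls(**data)
        if sim is not None:
            cfg.simulation = SimulationConfig(tree=cfg.tree(), **sim)
        return cfg


@dataclass
class PipelineResult:
    run_dir: Path
    summary: dict
    psgs: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return self.summary["counts"]


def _analyze_genes(alignments, tree, alpha, run_scan, run_rates):
    """Per-gene branch-site and free-ratio fits sharing one likelihood engine.

    The stage-1 (branch-length) fit, pattern compression and matrix
    eigendecomposition caches are reused between the two analyses of each
    gene, which roughly halves the per-gene cost of a full run.
    """
    scans, branch_rates = [], {}
    for aln in alignments:
        try:
            engine = LikelihoodEngine(aln, tree)
            m0, _ = fit_two_ratio(engine)
            if run_scan:
                scans.append(fit_branch_site(aln, tree, alpha=alpha, engine=engine, m0=m0))
            if run_rates:
                branch_rates[aln.gene_id] = fit_free_ratio(aln, tree, engine=engine, m0=m0, maxiter=40)
        except Exception as exc:  # optimizer failure: exclude and log
            logger.warning("model fits failed for %s: %s", aln.gene_id, exc)
    return scans, branch_rates


def run_pipeline(
    config: RunConfig,
    alignments: list[CodonAlignment] | None = None,
    annotations: dict[str, list[str]] | None = None,
    study: OrthologStudy | None = None,
) -> PipelineResult:
    """Run the enabled stages in order and write per-stage outputs.

    Inputs are either explicit ``alignments`` (+ ``annotations``) or a
    synthetic study; with neither, the simulation stage generates one from
    ``config.simulation`` (or its defaults).  The summary JSON records the
    gene count surviving each filter, the PSG list, category calls, and —
    when simulation truth is available — PSG recall and precision.
    """
    run_dir = Path(config.outdir)
    run_dir.mkdir(parents=True, exist_ok=True)
    tree = config.tree()
    counts: dict[str, int] = {}
    summary: dict = {"counts": counts, "config": {k: v for k, v in asdict(config).items() if k != "simulation"}}

    if alignments is None:
        if study is None:
            sim_cfg = config.simulation or SimulationConfig(tree=tree, seed=config.seed)
            study = generate_ortholog_study(sim_cfg, run_dir=run_dir / "simulated")
        alignments = study.alignments
        annotations = study.annotations
    annotations = annotations or {}
    counts["input_genes"] = len(alignments)

    # --- QC ---------------------------------------------------------------
    if config.run_qc:
        trimmed = [qc_mod.trim_alignment_blocks(a) for a in alignments]
        kept, rejected = qc_mod.filter_orthologs(trimmed, min_length_bp=config.min_len_bp)
        counts["after_trim_and_filter"] = len(kept)
        verdicts = [qc_mod.saturation_test(a, tree, threshold=config.saturation_threshold) for a in kept]
        with open(run_dir / "saturation.tsv", "w") as fh:
            fh.write("gene_id\tmax_branch_length\tsaturated\treason\n")
            for v in verdicts:
                fh.write(f"{v.gene_id}\t{v.max_branch_length:.4f}\t{int(v.saturated)}\t{v.reason or 'NA'}\n")
        kept = [a for a, v in zip(kept, verdicts) if not v.saturated]
        counts["after_saturation"] = len(kept)
        with open(run_dir / "qc_rejects.tsv", "w") as fh:
            fh.write("gene_id\treason\n")
            for gene, reason in rejected:
                fh.write(f"{gene}\t{reason}\n")
        alignments = kept
    else:
        counts["after_trim_and_filter"] = len(alignments)
        counts["after_saturation"] = len(alignments)

    # --- per-gene model fits ------------------------------------------------
    fits, gene_rates = _analyze_genes(
        alignments, tree, config.psg_alpha, config.run_scan, config.run_rates
    )

    # --- branch-site scan ---------------------------------------------------
    psgs: list[str] = []
    if config.run_scan:
        with open(run_dir / "branch_site.tsv", "w") as fh:
            fh.write("gene_id\tlnL_alt\tlnL_null\tlrt\tp_value\tomega2\tpsg_flag\n")
            for f in fits:
                fh.write(
                    f"{f.gene_id}\t{f.lnl_alt:.6f}\t{f.lnl_null:.6f}\t{f.statistic:.6f}\t"
                    f"{f.p_value:.6g}\t{f.omega2:.4f}\t{int(f.psg)}\n"
                )
        fit_records = {
            f.gene_id: {
                "lnl_alt": f.lnl_alt, "lnl_null": f.lnl_null, "statistic": f.statistic,
                "p_value": f.p_value, "p0": f.p0, "p1": f.p1, "omega0": f.omega0,
                "omega2": f.omega2, "kappa": f.kappa, "psg": f.psg,
                "diagnostics": f.diagnostics,
            }
            for f in fits
        }
        (run_dir / "branch_site_fits.json").write_text(
            json.dumps(fit_records, indent=2, sort_keys=True) + "\n")
        psgs = [f.gene_id for f in fits if f.psg]
        counts["psgs"] = len(psgs)
        summary["psgs"] = psgs
        if study is not None and not study.truth.empty:
            truth = study.true_psgs()
            analysed = {a.gene_id for a in alignments}
            truth_in = truth & analysed
            hit = len(truth_in & set(psgs))
            summary["psg_recall"] = hit / len(truth_in) if truth_in else None
            summary["psg_precision"] = hit / len(psgs) if psgs else None

    # --- lineage rates -------------------------------------------------------
    if config.run_rates and alignments:
        lineage = rates_mod.concatenate_and_fit(alignments, tree, focal_taxa=config.focal_taxa)
        summary["lineage_rates"] = {
            k: {"mean_ka": v.mean_ka, "mean_ks": v.mean_ks, "mean_ka_ks": v.mean_ka_ks}
            for k, v in lineage.items()
        }
        rates_a: dict = {}
        rates_b: dict = {}
        ta, tb = config.focal_taxa
        with open(run_dir / "branch_rates.tsv", "w") as fh:
            fh.write("gene_id\tbranch\tt\tomega\tKa\tKs\tn_hat\ts_hat\n")
            for aln in alignments:
                branch_rates = gene_rates.get(aln.gene_id)
                if branch_rates is None:
                    continue
                for label, br in branch_rates.items():
                    fh.write(
                        f"{aln.gene_id}\t{label}\t{br.t:.5f}\t{br.omega:.4f}\t{br.ka:.5f}\t"
                        f"{br.ks:.5f}\t{br.n_hat:.3f}\t{br.s_hat:.3f}\n"
                    )
                if ta in branch_rates:
                    rates_a[aln.gene_id] = branch_rates[ta]
                if tb in branch_rates:
                    rates_b[aln.gene_id] = branch_rates[tb]
        category = rates_mod.category_rate_test(
            annotations, rates_a, rates_b, min_orthologs=config.min_category_orthologs
        )
        rates_mod.write_category_tsv(category, run_dir / "category_rates.tsv")
        summary["accelerated_categories"] = {
            "A_" + ta: [r.term_id for r in category if r.p_holm < 0.05 and r.accelerated == "A"],
            "B_" + tb: [r.term_id for r in category if r.p_holm < 0.05 and r.accelerated == "B"],
        }

    # --- enrichment ----------------------------------------------------------
    if config.run_enrich:
        background = [a.gene_id for a in alignments]
        results = enrich_mod.fisher_overrepresentation(psgs, background, annotations) if background else []
        scores = enrich_mod.classify_over_represented(
            results, es_threshold=config.es_threshold, alpha=config.psg_alpha
        )
        enrich_mod.write_enrichment_tsv(results, scores, run_dir / "enrichment.tsv")
        summary["over_represented_terms"] = [s.cluster_id for s in scores if s.over_represented]

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n")
    return PipelineResult(run_dir=run_dir, summary=summary, psgs=psgs)


# ---------------------------------------------------------------------------
# Sanger concordance
# ---------------------------------------------------------------------------

@dataclass
class FragmentReport:
    fragment_id: str
    aligned_bp: int
    mismatches: int


@dataclass
class ConcordanceReport:
    fragments: list[FragmentReport]
    failed: list[str]

    @property
    def total_bp(self) -> int:
        return sum(f.aligned_bp for f in self.fragments)

    @property
    def total_mismatches(self) -> int:
        return sum(f.mismatches for f in self.fragments)

    @property
    def percent_consistency(self) -> float:
        """100 * (1 - mismatches / total length), half-up to 2 decimals."""
        if self.total_bp == 0:
            return 100.0
        frac = 100.0 * (1.0 - self.total_mismatches / self.total_bp)
        return float(Decimal(repr(frac)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _end_free_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def sanger_concordance(
    assembly_fragments: dict[str, str],
    sanger_fragments: dict[str, str],
    pairing: dict[str, str],
) -> ConcordanceReport:
    """Mismatch accounting between assembly and Sanger re-sequenced fragments.

    Each pair is globally aligned with free end gaps; within the mutually
    covered region every mismatching column counts, gaps included.
    Fragments without a partner are reported as failed and excluded from
    the totals.
    """
    aligner = _end_free_aligner()
    fragments: list[FragmentReport] = []
    failed = [a for a in sorted(assembly_fragments) if a not in pairing]
    for frag_id in sorted(pairing):
        sanger_id = pairing[frag_id]
        if frag_id not in assembly_fragments or sanger_id not in sanger_fragments:
            failed.append(frag_id)
            continue
        alignment = aligner.align(assembly_fragments[frag_id], sanger_fragments[sanger_id])[0]
        a, b = str(alignment[0]), str(alignment[1])
        a_arr = np.frombuffer(a.encode(), dtype="S1")
        b_arr = np.frombuffer(b.encode(), dtype="S1")
        a_res = np.flatnonzero(a_arr != b"-")
        b_res = np.flatnonzero(b_arr != b"-")
        start = max(a_res[0], b_res[0])
        end = min(a_res[-1], b_res[-1]) + 1
        cols = slice(start, end)
        length = end - start
        mismatches = int((a_arr[cols] != b_arr[cols]).sum())
        fragments.append(FragmentReport(frag_id, int(length), mismatches))
    for frag_id in failed:
        logger.warning("concordance: fragment %s unpaired, excluded from totals", frag_id)
    return ConcordanceReport(fragments=fragments, failed=failed)
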