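# Methods

This note records the models, conventions and numerical choices behind
`codonscan`, in the order the pipeline applies them.

## Codon substitution model and branch-length convention

The substitution process on the 61 sense codons of the standard nuclear
code is the Goldman–Yang Markov model: q(i→j) = 0 unless i and j differ at
exactly one nucleotide position and neither is a stop codon, otherwise
q(i→j) ∝ π_j κ^[transition] ω^[nonsynonymous].  κ > 0 is the
transition/transversion rate ratio, ω ≥ 0 the nonsynonymous/synonymous
rate ratio, and π the stationary codon frequencies — by default estimated
from the alignment in the F3x4 style (position-specific nucleotide
frequencies with a 0.5 pseudocount so every sense codon stays strictly
positive; an equal-frequency option exists for controlled experiments).

Every generator is scaled to unit mean rate, −Σ_i π_i q_ii = 1.  Branch
lengths are expressed on the **neutral scale**: a branch of length t
accumulates t expected substitutions per codon for a site evolving at
ω = 1, and t·g(ω) substitutions for a site class with ratio ω, where

    g(ω) = ω·a + b,   a + b = 1,

and (a, b) are the nonsynonymous/synonymous shares of the neutral flux
(functions `flux_split` / `relative_rate`).  This is the generative model
the branch-site test assumes — purifying classes evolve more slowly,
positively selected classes faster — expressed with a neutral rather than
mixture-averaged time unit.  Two consequences worth noting:

* expected counts per codon on a branch are t·ω·a (nonsynonymous) and
  t·b (synonymous), so with site counts 3a and 3b per codon the
  decomposition gives **Ka = ω·t/3 and Ks = t/3 exactly**, and Ka/Ks = ω
  by construction;
* fitted branch lengths are comparable across models of the same gene but
  are not "substitutions per codon averaged over classes".

Transition matrices P(t) = exp(Qt) come from a symmetric eigendecomposition
of the reversible generator (D^{1/2} Q D^{−1/2} with D = diag π), which
makes evaluation at many branch lengths cheap inside the optimisers;
row-stochasticity, the semigroup property and detailed balance hold to
1e−10 and are asserted in tests.

## Tree likelihood

Likelihoods are computed by Felsenstein pruning over compressed site
patterns.  Gap codons, ambiguity codons and taxa missing from an alignment
enter as all-ones partial likelihoods (marginalised).  Because every model
here is reversible, the likelihood is invariant to the rooting; the code
exploits this by re-hanging the tree at the parent of the foreground
branch so the rest-of-tree partial can be cached while the foreground
branch's length and ω vary (see below).  Correctness is anchored by
brute-force enumeration over internal-node states on four-taxon trees
(relative error < 1e−10) and a closed-form two-taxon oracle.

## Branch-site test

The alternative model is branch-site model A: site classes 0 (ω₀ ∈ (0,1)
everywhere), 1 (ω = 1 everywhere), 2a (background ω₀, foreground ω₂) and
2b (background 1, foreground ω₂), with weights constrained by
p₂ₐ : p₂_b = p₀ : p₁ — parametrised as (r, s) with p₀ = rs, p₁ = (1−r)s.
The null fixes ω₂ = 1.  The test statistic is 2Δℓ = 2(lnL_alt − lnL_null),
clamped at 0, referred to χ² with 1 df (the conservative choice rather
than the 50:50 boundary mixture); a gene is called a PSG when p < 0.05.

Fitting is staged for throughput:

1. **Stage 1 (branch lengths, κ):** a two-ratio fit — one background ω,
   a separate foreground ω, all branch lengths and κ free — by L-BFGS-B on
   log-transformed parameters, initialised from least-squares branch
   lengths on corrected pairwise codon distances.  Letting the foreground
   branch carry its own ω at this stage keeps its length estimate on the
   neutral scale instead of absorbing foreground selection into t.
2. **Stage 2 (site classes):** background branch lengths and κ are fixed
   at stage-1 values; the null optimises (ω₀, t_fg, r, s) and the
   alternative (ω₀, ω₂, t_fg, r, s), each from three deterministic starts.
   The foreground branch length t_fg is re-estimated **within each model**
   — fixing it across models turned out to be the single largest source of
   both power loss and spurious rejections, because stage-1 estimates of
   t_fg sit on an ω·t ridge.  One alternative-model start continues from
   the null optimum with ω₂ → 1⁺, which guarantees lnL_alt ≥ lnL_null up
   to optimiser tolerance.

With the foreground branch terminal (the default), each candidate
(ω₀, ω₂, t_fg) is evaluated by combining a cached rest-of-tree partial
with a single fresh transition matrix, so a full branch-site test of a
250-codon gene takes well under a second.

Parameter transforms and bounds: log t ∈ [ln 1e−6, ln 20], log κ ∈
[ln 0.1, ln 20], log ω₀ ≤ ln 0.999, ω₂ = 1 + e^u with u ≤ ln 49, logits of
r and s in [−10, 10]; L-BFGS-B with ftol 1e−10.  An optimiser failure
leaves the gene flagged in the fit diagnostics and the pipeline logs and
excludes it.

## Free-ratio model and lineage rates

The free-ratio model gives every branch its own ω (shared κ, branch
lengths free), fitted jointly on log scale with per-ω eigendecomposition
caching, followed by a short joint polish that frees κ.  Reported per
branch: t, ω, Ka = ωt/3, Ks = t/3, and expected substitution counts
n̂ = t·ω·a·L and ŝ = t·b·L for a gene of L codons.  A two-taxon alignment
has a single identifiable path; it is fitted as one (t, ω, κ) triple.
Zero-length branches report ω as NaN with Ka = Ks = 0.

Lineage-level means are **not** averages of per-gene estimates: they come
from one free-ratio fit of the codon-wise concatenation of all analysed
genes, and the reported mean Ka/Ks is that fit's branch ω (not the ratio
of mean Ka to mean Ks).

The category acceleration test compares expected nonsynonymous counts on
the two focal terminal branches.  Per functional term with more than 20
analysed member genes, n_A = Σ n̂ over members (rounded half-even; ML fits
give expectations, not integers), likewise n_B; the exact two-sided
binomial test of n_A successes in n_A + n_B trials against
p₀ = N_A/(N_A+N_B) (genome-wide totals) is Holm-corrected across terms.
The accelerated lineage is A when n_A/(n_A+n_B) > p₀, else B.  Expected
counts from the free-ratio fit were chosen over reconstructed substitution
counts; the statistic is isolated behind one function so it can be
swapped.

## Counting cross-check (NG86 style)

`ng86_pairwise` is the deliberately simple, likelihood-free cross-check:
per-codon synonymous-site fractions, observed differences averaged over
minimal substitution paths (paths through stop codons excluded when
avoidable), Jukes–Cantor correction, NaN markers at the p ≥ 0.75
saturation bound.  Site counting optionally weights transitions by κ;
the unweighted default is the classic count, which is biased low for
dN/dS when the mutation process is transition-rich (measured ≈ 0.84 for a
true ω = 1 at κ = 2), while the κ-weighted count recovers ≈ 0.97.
Cross-checks against the likelihood fits therefore pass the generating or
estimated κ.

## Alignment QC

* **Consensus calling:** the modal base per site from read-support counts;
  ties break alphabetically (A < C < G < T) — the deterministic rule is
  documented because reproducibility requires one; zero support yields N.
* **Block trimming:** a simplified stand-in for Gblocks' `codons` mode.
  A codon column is reliable when its gap fraction is ≤ `max_gap_fraction`
  (default 0) and ≥ 50 % of taxa share the majority amino acid; maximal
  runs of ≥ `min_block` (default 5) reliable columns are kept.  The filter
  is idempotent.  Exact Gblocks replication is a non-goal.
* **Stop/length filter:** genes with an internal stop codon in any
  sequence, or trimmed length < 200 bp, are discarded with logged reasons.
  The boundary sits at exactly 200 (a 198-bp alignment is discarded, a
  201-bp alignment kept).
* **Saturation screen:** third codon positions are extracted and GTR+F
  branch lengths fitted on the fixed species topology (empirical base
  frequencies with pseudocount; five free exchangeabilities with GT = 1;
  branch lengths bounded in [1e−8, 50]; three deterministic starts).  A
  gene is saturated when any fitted branch length reaches 1.0; a
  non-convergent fit flags the gene conservatively.  GTR parameters are
  estimated per gene.

## Enrichment

Per term: the one-tailed hypergeometric tail (Fisher) and the EASE
variant with one success removed (the default "modified Fisher"), plus
Benjamini–Hochberg adjusted p-values reported alongside.  Cluster scores
use ES = −log₁₀ of the geometric mean of member-term p-values (p floored
at 1e−300); by default every term is its own cluster, so ES reduces to
−log₁₀ p.  A category is over-represented when ES > 1.3 **and** p < 0.05,
both strict.  Term clustering itself (fuzzy-kappa style) is out of scope;
clusters are caller-supplied groupings.  Classification uses the raw p,
with the BH column available for stricter readings.

## Orthology

Translated similarity is a six-frame (query) × three-forward-frame
(target) local Smith–Waterman on the translated peptides, BLOSUM62, gap
open 11 / extend 1, with stop-codon rows of the scoring matrix forced to a
large negative value so frames broken by stops cannot win.  Hit
coordinates are 0-based half-open nucleotide positions on the input
strings.  Significance thresholds are calibrated on shuffled-sequence
nulls (default: the 99.999th percentile of 10⁴ shuffled-pair scores)
rather than by e-value statistics, because Karlin–Altschul parameters for
this scorer are not available.  Best-reciprocal-hit pairs additionally
require coverage of ≥ 30 % of the shorter translated length — an
implementation default, not a literature value.  Ties for best hit drop
the sequence: only unambiguous 1:1 orthologs are kept.  A shared-5-mer
prescreen skips hopeless pairs before full alignment.

## Sanger concordance

Paired fragments are globally aligned with free end gaps (match 1,
mismatch −1, gap open 2 / extend 1); within the mutually covered region
every mismatching column counts, internal gaps included.  Percent
consistency is 100·(1 − mismatches/total length), rounded half-up to two
decimals.  Unpaired fragments are excluded from the totals and logged.

## Synthetic studies: what the generator does and does not emulate

The simulator draws per-site branch-site class assignments
(p₀, p₁, p₂ₐ, p₂_b with the model A constraint), evolves root draws from π
forward along the tree with the exact transition matrices, labels a
deterministic quota of ⌊psg_fraction·n⌋ genes (first indices of a seeded
permutation) as foreground-selected with ω₂ > 1 (the rest get ω₂ = 1),
and emits decoy transcripts (orthologs evolved by 0.15 neutral
substitutions/codon ≈ 95 % nucleotide identity, paralog copies at 2.0
≈ 60 %, truncations, random untranslated flanks, unrelated random
sequence) plus a randomised gene→term annotation table in which a
configurable number of terms draw a configurable share of members from
the true PSG set.  Everything is bit-reproducible from the config seed.

Default study conditions (all configurable): the five-taxon topology with
branch lengths 0.30 (foreground terminal), 0.15 (sister terminal), 0.25 /
0.15 (internals), 0.45–0.55 (outgroup terminals) neutral
substitutions/codon; κ = 2; background ω₀ = 0.2; p₀ = 0.45, p₁ = 0.30;
foreground ω₂ = 5 for selected genes; gene lengths 200–300 codons; equal
codon frequencies.  These were chosen once, at design time, to place the
branch-site test in an informative regime — a foreground branch much
shorter than ~0.1 carries so few substitutions that no analysis can
detect selection on it — while staying within the range used by published
power studies; real transcripts are on average longer (~540 codons), so
the length default is conservative.  Under these conditions the scan shows
~90 % per-gene power at ω₂ = 5 and a null rejection rate at or below the
nominal 5 %.

What passing tests do **not** show about real data: the generator has no
alignment error, no indels (gaps only via explicit decoy truncation), no
assembly or consensus-calling noise, no rate variation beyond the
branch-site classes, no GC-content heterogeneity across genes, flat
annotations rather than a term graph, and no expression information.
Conclusions about calibration and power transfer to real data only to the
extent these factors are second-order.

## Problem sizes used in the test suite

Chosen as the package's own benchmark sizes: null calibration with 200
genes at the default length range; power with 50 genes of 500 codons at
ω₂ = 5; rate recovery on two-taxon alignments of 20,000 codons; the
saturation screen on 50 replicates of 500 third-position sites; the
end-to-end study with 200 genes, 20 % selected, terms of 25–40 genes.
The acceptance script runs a 120-gene study by default (`--n-genes`
raises it).

## Known limitations

* No Bayes empirical Bayes identification of selected **sites**; the unit
  of inference is the gene.
* Stage-1 background branch lengths and κ are not re-freed in the
  site-class stage (only the foreground branch length is); this is the
  main approximation relative to a full joint optimisation, chosen for
  throughput and validated by the calibration and power results.
* The LRT uses χ²₁ rather than the boundary mixture, which is
  conservative.
* The block-trimming surrogate approximates, not replicates, Gblocks; the
  binomial category statistic is one concrete reading of "comparison of
  evolutionary rates based on nonsynonymous substitution" and is isolated
  so alternatives can be swapped in.
* NG86-style counting saturates (NaN) beyond p = 0.75 and is biased
  without the κ-weighted site counts.
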