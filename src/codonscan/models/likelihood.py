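"""Felsenstein pruning over an arbitrary state space.

Works for the 61-state codon process and the 4-state nucleotide process
alike.  Site patterns are compressed before any likelihood work: an
alignment column appears once with a multiplicity weight, which is the main
lever that keeps per-gene optimisation affordable.

Missing data (gap codons, ambiguity codons, taxa absent from the alignment)
enter as all-ones partial likelihoods, i.e. they are marginalised over.
"""

from __future__ import annotations

import numpy as np

from ..alignment import CodonAlignment
from ..trees import PhyloTree
from . import matrices


def compress_patterns(columns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    ``columns`` is (n_taxa, n_sites) of integer states (-1 = missing).
    Returns (patterns, weights) with patterns (n_taxa, n_patterns).
    """
    patterns, counts = np.unique(columns, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def site_likelihoods(
    tree: PhyloTree,
    P_by_edge: dict[int, np.ndarray],
    patterns: np.ndarray,
    leaf_rows: dict[int, int | None],
    pi: np.ndarray,
    return_root_partial: bool = False,
) -> np.ndarray:
    """Per-pattern likelihoods by postorder pruning.

    ``leaf_rows`` maps each leaf node id to its row in ``patterns`` (or
    ``None`` for a leaf with no data).  With ``return_root_partial`` the
    (n_patterns, n_states) product of child messages at the root is
    returned instead of the pi-weighted site likelihoods.
    """
    n_pat = patterns.shape[1]
    n_states = pi.size
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if not tree.children[node]:
            continue
        prod: np.ndarray | None = None
        for child in tree.children[node]:
            P = P_by_edge[child]
            if not tree.children[child]:  # leaf child: fold data through P
                row = leaf_rows.get(child)
                if row is None:
                    continue  # marginalised leaf contributes a factor of 1
                states = patterns[row]
                msg = P.T[np.maximum(states, 0)]
                msg[states < 0] = 1.0
            else:
                msg = partial.pop(child) @ P.T
            prod = msg if prod is None else prod * msg
        partial[node] = prod if prod is not None else np.ones((n_pat, n_states))
    if return_root_partial:
        return partial[0]
    return partial[0] @ pi


class SiteClassModel:
    """Mixture of codon site classes.

    Each class is (weight, omega_background, omega_foreground); branches not
    flagged foreground use the background omega.  A single-class model with
    equal background/foreground omega is the one-ratio (M0) model.
    """

    def __init__(self, params: matrices.CodonModelParams, classes: list[tuple[float, float, float]]):
        weights = np.array([w for w, _, _ in classes], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-8):
            raise ValueError("class weights must be a probability vector")
        self.params = params
        self.classes = [(float(w), float(ob), float(of)) for w, ob, of in classes]


class LikelihoodEngine:
    """Pattern-compressed likelihood evaluator bound to one alignment + tree."""

    def __init__(self, alignment: CodonAlignment, tree: PhyloTree, pi: np.ndarray | None = None):
        extra = set(alignment.taxa) - set(tree.leaf_labels)
        if extra:
            raise ValueError(f"alignment taxa not in tree: {sorted(extra)}")
        self.alignment = alignment
        self.tree = tree
        self.patterns, self.weights = compress_patterns(alignment.codon_matrix())
        taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
        self.leaf_rows: dict[int, int | None] = {
            leaf: taxon_row.get(tree.labels[leaf]) for leaf in tree.leaves
        }
        from .. import genetics

        self.pi = np.asarray(pi, dtype=float) if pi is not None else genetics.f3x4_frequencies(alignment.sequences)
        self._spectral_cache: dict[tuple[float, float], matrices.SpectralMatrix] = {}
        self._flux_cache: dict[float, tuple[float, float]] = {}

    def relative_rate(self, kappa: float, omega: float) -> float:
        """Rate of the omega class relative to neutral; branch lengths are
        expressed on the neutral (omega = 1) scale."""
        ab = self._flux_cache.get(float(kappa))
        if ab is None:
            ab = matrices.flux_split(matrices.CodonModelParams(kappa, self.pi))
            self._flux_cache[float(kappa)] = ab
        a, b = ab
        return omega * a + b

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())

    def spectral(self, kappa: float, omega: float) -> matrices.SpectralMatrix:
        key = (float(kappa), float(omega))
        hit = self._spectral_cache.get(key)
        if hit is None:
            if len(self._spectral_cache) > 512:
                self._spectral_cache.clear()
            hit = matrices.codon_spectral(matrices.CodonModelParams(kappa, self.pi), omega)
            self._spectral_cache[key] = hit
        return hit

    def class_site_likelihoods(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float,
        lengths: dict[int, float],
    ) -> np.ndarray:
        """Per-pattern likelihood under a single site class."""
        bg = self.spectral(kappa, omega_background)
        fg = self.spectral(kappa, omega_foreground)
        g_bg = self.relative_rate(kappa, omega_background)
        g_fg = self.relative_rate(kappa, omega_foreground)
        P_by_edge = {
            node: (
                fg.transition_matrix(g_fg * lengths[node])
                if node == self.tree.foreground
                else bg.transition_matrix(g_bg * lengths[node])
            )
            for node in self.tree.edges
        }
        return site_likelihoods(self.tree, P_by_edge, self.patterns, self.leaf_rows, self.pi)

    def free_ratio_site_likelihoods(
        self, kappa: float, omega_by_edge: dict[int, float], lengths: dict[int, float]
    ) -> np.ndarray:
        P_by_edge = {
            node: self.spectral(kappa, omega_by_edge[node]).transition_matrix(
                self.relative_rate(kappa, omega_by_edge[node]) * lengths[node]
            )
            for node in self.tree.edges
        }
        return site_likelihoods(self.tree, P_by_edge, self.patterns, self.leaf_rows, self.pi)

    def mixture_loglik(self, model: SiteClassModel, lengths: dict[int, float]) -> float:
        mix = np.zeros(self.patterns.shape[1])
        for w, ob, of in model.classes:
            if w == 0.0:
                continue
            mix += w * self.class_site_likelihoods(model.params.kappa, ob, of, lengths)
        return float(self.weights @ np.log(np.maximum(mix, 1e-300)))


def log_likelihood(alignment: CodonAlignment, tree: PhyloTree, model: SiteClassModel) -> float:
    """Mixture log-likelihood of a codon alignment on a tree with lengths.

    Branch lengths are taken from the tree; gap/ambiguous codons are treated
    as missing data.
    """
    engine = LikelihoodEngine(alignment, tree, pi=model.params.pi)
    lengths = {node: float(tree.lengths[node]) for node in tree.edges}
    return engine.mixture_loglik(model, lengths)
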