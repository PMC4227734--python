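"""Maximum-likelihood fits of codon models.

Three fits are provided:

* :func:`fit_m0` — one-ratio model; also supplies branch lengths and kappa
  for the staged branch-site and free-ratio fits.
* :func:`fit_branch_site` — branch-site model A on a flagged foreground
  branch (site classes 0, 1, 2a, 2b with the proportion constraint
  p2a : p2b = p0 : p1) against its null with omega2 = 1, and the chi^2(1)
  likelihood-ratio test for positive selection.
* :func:`fit_free_ratio` — an independent omega per branch with shared
  kappa, plus the Ka/Ks decomposition and expected substitution counts.

All optimisation runs on log / logit transformed parameters with bounded
quasi-Newton (L-BFGS-B).  The branch-site site-class stage keeps branch
lengths and kappa at their one-ratio estimates, which makes the scan fast
enough to run genome-scale synthetic studies; the free-ratio fit re-frees
the branch lengths.  Class likelihood vectors and matrix eigendecompositions
are cached, so coordinate-wise gradient evaluations cost almost nothing for
the parameters that do not touch the substitution process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from ..alignment import CodonAlignment
from ..trees import PhyloTree
from . import matrices
from .likelihood import LikelihoodEngine, site_likelihoods

_LOG_T_BOUNDS = (np.log(1e-6), np.log(20.0))
_LOG_KAPPA_BOUNDS = (np.log(0.1), np.log(20.0))
_LOG_OMEGA_BOUNDS = (np.log(1e-4), np.log(50.0))
_LOG_OMEGA0_BOUNDS = (np.log(1e-5), np.log(0.999))
_LOGIT_BOUNDS = (-10.0, 10.0)


# ---------------------------------------------------------------------------
# initial branch lengths from pairwise divergence
# ---------------------------------------------------------------------------

def _pairwise_distance_init(engine: LikelihoodEngine) -> dict[int, float]:
    """Least-squares branch lengths from corrected pairwise codon distances."""
    tree = engine.tree
    patterns, weights = engine.patterns, engine.weights
    pairs, A = tree.pairwise_path_matrix()
    label_row = {tree.labels[leaf]: engine.leaf_rows[leaf] for leaf in tree.leaves}
    d = np.full(len(pairs), np.nan)
    for k, (a, b) in enumerate(pairs):
        ra, rb = label_row.get(a), label_row.get(b)
        if ra is None or rb is None:
            continue
        sa, sb = patterns[ra], patterns[rb]
        ok = (sa >= 0) & (sb >= 0)
        total = weights[ok].sum()
        if total == 0:
            continue
        p = float(weights[ok & (sa != sb)].sum() / total)
        # Poisson correction at unit codon rate; ~0.98 is the asymptote of
        # the probability two random sense codons differ
        d[k] = -np.log(max(1.0 - p / 0.98, 0.05))
    keep = np.isfinite(d)
    n_edges = A.shape[1]
    if keep.sum() < n_edges:
        return {e: 0.1 for e in tree.edges}
    sol, *_ = np.linalg.lstsq(A[keep], d[keep], rcond=None)
    sol = np.clip(sol, 1e-4, 10.0)
    return dict(zip(tree.edges, sol))


# ---------------------------------------------------------------------------
# M0 (one-ratio)
# ---------------------------------------------------------------------------

@dataclass
class M0Fit:
    lnl: float
    kappa: float
    omega: float
    lengths: dict[int, float]
    converged: bool


def fit_m0(
    engine: LikelihoodEngine,
    kappa0: float = 2.0,
    omega0: float = 0.3,
    maxiter: int = 80,
) -> M0Fit:
    edges = engine.tree.edges
    n = len(edges)
    t_init = _pairwise_distance_init(engine)
    x0 = np.concatenate(
        [np.log([max(t_init[e], 1e-4) for e in edges]), [np.log(kappa0), np.log(omega0)]]
    )
    bounds = [_LOG_T_BOUNDS] * n + [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS]
    logw = engine.weights

    def nll(x: np.ndarray) -> float:
        lengths = dict(zip(edges, np.exp(x[:n])))
        kappa, omega = np.exp(x[n]), np.exp(x[n + 1])
        L = engine.class_site_likelihoods(kappa, omega, omega, lengths)
        return -float(logw @ np.log(np.maximum(L, 1e-300)))

    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    return M0Fit(
        lnl=-float(res.fun),
        kappa=float(np.exp(res.x[n])),
        omega=float(np.exp(res.x[n + 1])),
        lengths=dict(zip(edges, np.exp(res.x[:n]))),
        converged=bool(res.success),
    )


def fit_two_ratio(
    engine: LikelihoodEngine,
    kappa0: float = 2.0,
    omega0: float = 0.3,
    maxiter: int = 80,
) -> tuple[M0Fit, float]:
    """One-ratio background plus a separate foreground omega.

    Used as the branch-length stage of the branch-site fit: letting the
    foreground branch carry its own omega keeps its length estimate on the
    neutral scale instead of absorbing foreground selection into t.
    Returns the fit (with the background omega) and the foreground omega.
    """
    tree = engine.tree
    if tree.foreground is None:
        raise ValueError("tree has no foreground branch flagged")
    edges = tree.edges
    n = len(edges)
    t_init = _pairwise_distance_init(engine)
    x0 = np.concatenate(
        [
            np.log([max(t_init[e], 1e-4) for e in edges]),
            [np.log(kappa0), np.log(omega0), np.log(omega0)],
        ]
    )
    bounds = [_LOG_T_BOUNDS] * n + [_LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS, _LOG_OMEGA_BOUNDS]
    site_w = engine.weights
    fg = tree.foreground
    omega_by_edge = {e: 0.0 for e in edges}

    def nll(x: np.ndarray) -> float:
        lengths = dict(zip(edges, np.exp(x[:n])))
        kappa, w_bg, w_fg = np.exp(x[n]), np.exp(x[n + 1]), np.exp(x[n + 2])
        for e in edges:
            omega_by_edge[e] = w_fg if e == fg else w_bg
        L = engine.free_ratio_site_likelihoods(kappa, omega_by_edge, lengths)
        return -float(site_w @ np.log(np.maximum(L, 1e-300)))

    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    fit = M0Fit(
        lnl=-float(res.fun),
        kappa=float(np.exp(res.x[n])),
        omega=float(np.exp(res.x[n + 1])),
        lengths=dict(zip(edges, np.exp(res.x[:n]))),
        converged=bool(res.success),
    )
    return fit, float(np.exp(res.x[n + 2]))


# ---------------------------------------------------------------------------
# branch-site model A
# ---------------------------------------------------------------------------

@dataclass
class BranchSiteFit:
    gene_id: str
    lnl_alt: float
    lnl_null: float
    statistic: float
    p_value: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    psg: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def p2a(self) -> float:
        rest = max(1.0 - self.p0 - self.p1, 0.0)
        tot = self.p0 + self.p1
        return rest * self.p0 / tot if tot > 0 else 0.0

    @property
    def p2b(self) -> float:
        rest = max(1.0 - self.p0 - self.p1, 0.0)
        tot = self.p0 + self.p1
        return rest * self.p1 / tot if tot > 0 else 0.0


class _ClassVectors:
    """Branch-site class likelihood vectors with the foreground branch free.

    Background branch lengths and kappa stay at their stage-1 estimates; the
    foreground branch length is a parameter of both the null and the
    alternative model.  When the foreground branch is terminal the tree is
    rerooted at its parent so that, for a given background omega, the
    rest-of-tree partial is computed once and any (omega_fg, t_fg) pair
    costs only one transition matrix and a gather — this is what keeps the
    genome-scale scans cheap.
    """

    def __init__(self, engine: LikelihoodEngine, kappa: float, lengths: dict[int, float]):
        self.engine = engine
        self.kappa = kappa
        self.lengths = lengths
        tree = engine.tree
        fg = tree.foreground
        self._rest: dict[float, np.ndarray] = {}
        self._vec: dict[tuple, np.ndarray] = {}
        self.terminal_fg = not tree.children[fg]
        if self.terminal_fg:
            fitted = tree.with_lengths(np.array([lengths[e] for e in tree.edges]))
            R, id_map = fitted.rerooted(int(tree.parent[fg]))
            self.R = R
            fg_new = id_map[fg]
            taxon_row = {t: i for i, t in enumerate(engine.alignment.taxa)}
            self.leaf_rows_R = {
                leaf: (None if leaf == fg_new else taxon_row.get(R.labels[leaf]))
                for leaf in R.leaves
            }
            row = taxon_row.get(R.labels[fg_new])
            self.obs = engine.patterns[row] if row is not None else None
            self.R_lengths = {node: float(R.lengths[node]) for node in R.edges}
            self.fg_new = fg_new

    def _rest_partial(self, w_bg: float) -> np.ndarray:
        hit = self._rest.get(w_bg)
        if hit is None:
            if len(self._rest) > 64:
                self._rest.clear()
            eng = self.engine
            spec = eng.spectral(self.kappa, w_bg)
            g = eng.relative_rate(self.kappa, w_bg)
            P_by_edge = {
                node: spec.transition_matrix(g * self.R_lengths[node]) for node in self.R.edges
            }
            M = site_likelihoods(
                self.R, P_by_edge, eng.patterns, self.leaf_rows_R, eng.pi, return_root_partial=True
            )
            hit = M * eng.pi[None, :]
            self._rest[w_bg] = hit
        return hit

    def vec(self, w_bg: float, w_fg: float, t_fg: float) -> np.ndarray:
        """Site likelihood vector of one class at foreground length t_fg."""
        key = (w_bg, w_fg, t_fg)
        hit = self._vec.get(key)
        if hit is not None:
            return hit
        if len(self._vec) > 256:
            self._vec.clear()
        eng = self.engine
        if self.terminal_fg:
            R_vec = self._rest_partial(w_bg)
            if self.obs is None:
                hit = R_vec.sum(axis=1)
            else:
                g = eng.relative_rate(self.kappa, w_fg)
                P = eng.spectral(self.kappa, w_fg).transition_matrix(g * t_fg)
                hit = (R_vec * P.T[np.maximum(self.obs, 0)]).sum(axis=1)
                missing = self.obs < 0
                if missing.any():
                    hit[missing] = R_vec[missing].sum(axis=1)
        else:
            lengths = dict(self.lengths)
            lengths[eng.tree.foreground] = t_fg
            hit = eng.class_site_likelihoods(self.kappa, w_bg, w_fg, lengths)
        self._vec[key] = hit
        return hit


def _mixture_nll(weights, parts):
    mix = np.zeros_like(parts[0][1])
    for w, vec in parts:
        mix += w * vec
    return -float(weights @ np.log(np.maximum(mix, 1e-300)))


def fit_branch_site(
    alignment: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray | None = None,
    alpha: float = 0.05,
    n_starts: int = 3,
    maxiter: int = 80,
    engine: LikelihoodEngine | None = None,
    m0: M0Fit | None = None,
) -> BranchSiteFit:
    """Branch-site test of positive selection on the flagged foreground branch."""
    if tree.foreground is None:
        raise ValueError("tree has no foreground branch flagged")
    engine = engine or LikelihoodEngine(alignment, tree, pi=pi)
    if m0 is None:
        m0, omega_fg = fit_two_ratio(engine)
    else:
        omega_fg = m0.omega
    vectors = _ClassVectors(engine, m0.kappa, m0.lengths)
    site_w = engine.weights
    w0_init = float(np.clip(m0.omega, 0.02, 0.9))
    tfg_init = float(np.clip(m0.lengths[tree.foreground], 1e-4, 10.0))

    def null_nll(x: np.ndarray) -> float:
        w0, t_fg = float(np.exp(x[0])), float(np.exp(x[1]))
        r, s = float(expit(x[2])), float(expit(x[3]))
        parts = [
            (r * s, vectors.vec(w0, w0, t_fg)),
            (1.0 - r, vectors.vec(1.0, 1.0, t_fg)),
            (r * (1.0 - s), vectors.vec(w0, 1.0, t_fg)),
        ]
        return _mixture_nll(site_w, parts)

    def alt_nll(x: np.ndarray) -> float:
        w0 = float(np.exp(x[0]))
        w2 = 1.0 + float(np.exp(x[1]))
        t_fg = float(np.exp(x[2]))
        r, s = float(expit(x[3])), float(expit(x[4]))
        parts = [
            (r * s, vectors.vec(w0, w0, t_fg)),
            ((1.0 - r) * s, vectors.vec(1.0, 1.0, t_fg)),
            (r * (1.0 - s), vectors.vec(w0, w2, t_fg)),
            ((1.0 - r) * (1.0 - s), vectors.vec(1.0, w2, t_fg)),
        ]
        return _mixture_nll(site_w, parts)

    opts = {"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7}
    null_bounds = [_LOG_OMEGA0_BOUNDS, _LOG_T_BOUNDS, _LOGIT_BOUNDS, _LOGIT_BOUNDS]
    null_starts = [
        (w0_init, max(tfg_init, 0.01), 0.7, 0.85),
        (0.1, 0.1, 0.5, 0.7),
        (0.5, max(tfg_init, 0.05), 0.9, 0.95),
    ][: max(n_starts, 1)]
    best_null = None
    for w0, t_fg, r, s in null_starts:
        x0 = np.array([np.log(w0), np.log(t_fg), logit(r), logit(s)])
        res = minimize(null_nll, x0, method="L-BFGS-B", bounds=null_bounds, options=opts)
        if best_null is None or res.fun < best_null.fun:
            best_null = res
    nw0 = float(np.exp(best_null.x[0]))
    nt = float(np.exp(best_null.x[1]))
    nr, ns = float(expit(best_null.x[2])), float(expit(best_null.x[3]))

    alt_bounds = [
        _LOG_OMEGA0_BOUNDS,
        (np.log(1e-6), np.log(49.0)),
        _LOG_T_BOUNDS,
        _LOGIT_BOUNDS,
        _LOGIT_BOUNDS,
    ]
    d2_init = float(np.clip(omega_fg - 1.0, 0.5, 20.0))
    alt_starts = [
        (nw0, 1e-6, nt, nr, ns),  # continuation of the null optimum (omega2 -> 1)
        (nw0, d2_init, max(tfg_init, 0.01), nr, min(ns, 0.85)),
        (nw0, 4.0, max(nt, 0.02), 0.5, 0.7),
        (0.2, 0.5, 0.1, 0.8, 0.9),
    ][: max(n_starts, 1)]
    best_alt = None
    for w0, d2, t_fg, r, s in alt_starts:
        x0 = np.array([np.log(w0), np.log(d2), np.log(t_fg), logit(r), logit(s)])
        res = minimize(alt_nll, x0, method="L-BFGS-B", bounds=alt_bounds, options=opts)
        if best_alt is None or res.fun < best_alt.fun:
            best_alt = res

    lnl_null, lnl_alt = -float(best_null.fun), -float(best_alt.fun)
    statistic = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p_value = float(chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    aw0 = float(np.exp(best_alt.x[0]))
    aw2 = 1.0 + float(np.exp(best_alt.x[1]))
    atfg = float(np.exp(best_alt.x[2]))
    ar, as_ = float(expit(best_alt.x[3])), float(expit(best_alt.x[4]))
    return BranchSiteFit(
        gene_id=alignment.gene_id,
        lnl_alt=lnl_alt,
        lnl_null=lnl_null,
        statistic=statistic,
        p_value=p_value,
        p0=ar * as_,
        p1=(1.0 - ar) * as_,
        omega0=aw0,
        omega2=aw2,
        kappa=m0.kappa,
        psg=bool(p_value < alpha),
        diagnostics={
            "converged": bool(best_null.success and best_alt.success),
            "m0_lnl": m0.lnl,
            "m0_omega": m0.omega,
            "t_fg_null": nt,
            "t_fg_alt": atfg,
        },
    )


# ---------------------------------------------------------------------------
# free-ratio model
# ---------------------------------------------------------------------------

@dataclass
class BranchRates:
    label: str
    t: float
    omega: float
    ka: float
    ks: float
    n_hat: float
    s_hat: float


def _branch_rates(
    label: str, t: float, omega: float, kappa: float, pi: np.ndarray, n_codons: int
) -> BranchRates:
    """Ka/Ks decomposition on the neutral branch-length scale.

    With branch lengths in neutral-expected substitutions per codon and the
    mutation-level flux split (a, b) into nonsynonymous/synonymous
    opportunity, expected counts per codon are ``t * omega * a``
    (nonsynonymous) and ``t * b`` (synonymous), site counts per codon are
    ``3a`` and ``3b``, hence Ka = omega * t / 3 and Ks = t / 3 exactly, and
    Ka/Ks = omega by construction.
    """
    if t <= 2e-6:
        return BranchRates(label, 0.0, float("nan"), 0.0, 0.0, 0.0, 0.0)
    params = matrices.CodonModelParams(kappa, pi)
    a, b = matrices.flux_split(params)
    return BranchRates(
        label=label,
        t=t,
        omega=omega,
        ka=omega * t / 3.0,
        ks=t / 3.0,
        n_hat=t * omega * a * n_codons,
        s_hat=t * b * n_codons,
    )


def fit_free_ratio(
    alignment: CodonAlignment,
    tree: PhyloTree,
    pi: np.ndarray | None = None,
    optimize_kappa: bool = True,
    maxiter: int = 60,
    engine: LikelihoodEngine | None = None,
    m0: M0Fit | None = None,
) -> dict[str, BranchRates]:
    """One omega per branch, shared kappa; returns per-branch rates.

    Branches are keyed by leaf label for terminal branches and by the sorted
    tip set for internal branches.  On a two-taxon alignment the single path
    between the sequences is the only identifiable branch; it is fitted as
    one (t, omega) pair keyed ``"a--b"``.
    """
    engine = engine or LikelihoodEngine(alignment, tree, pi=pi)
    site_w = engine.weights
    n_codons = alignment.n_codons

    if len(tree.leaves) == 2:
        return _fit_free_ratio_pair(engine, n_codons, maxiter)

    m0 = m0 or fit_m0(engine)
    edges = engine.tree.edges
    n = len(edges)
    omega_init = float(np.clip(m0.omega, 1e-3, 10.0))
    x0 = np.concatenate(
        [np.log([max(m0.lengths[e], 1e-5) for e in edges]), np.full(n, np.log(omega_init))]
    )
    bounds = [_LOG_T_BOUNDS] * n + [_LOG_OMEGA_BOUNDS] * n

    def nll_fixed_kappa(x: np.ndarray, kappa: float) -> float:
        lengths = dict(zip(edges, np.exp(x[:n])))
        omegas = dict(zip(edges, np.exp(x[n : 2 * n])))
        L = engine.free_ratio_site_likelihoods(kappa, omegas, lengths)
        return -float(site_w @ np.log(np.maximum(L, 1e-300)))

    res = minimize(
        nll_fixed_kappa, x0, args=(m0.kappa,), method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    kappa = m0.kappa
    x_best = res.x
    if optimize_kappa:
        x0k = np.concatenate([res.x, [np.log(m0.kappa)]])

        def nll_joint(x: np.ndarray) -> float:
            return nll_fixed_kappa(x[:-1], float(np.exp(x[-1])))

        res2 = minimize(
            nll_joint, x0k, method="L-BFGS-B", bounds=bounds + [_LOG_KAPPA_BOUNDS],
            options={"maxiter": 15, "ftol": 1e-11, "gtol": 1e-7},
        )
        if res2.fun <= res.fun:
            x_best, kappa = res2.x[:-1], float(np.exp(res2.x[-1]))

    t_hat = np.exp(x_best[:n])
    w_hat = np.exp(x_best[n : 2 * n])
    return {
        engine.tree.edge_label(e): _branch_rates(
            engine.tree.edge_label(e), float(t), float(w), kappa, engine.pi, n_codons
        )
        for e, t, w in zip(edges, t_hat, w_hat)
    }


def _fit_free_ratio_pair(engine: LikelihoodEngine, n_codons: int, maxiter: int) -> dict[str, BranchRates]:
    tree = engine.tree
    edges = tree.edges
    site_w = engine.weights
    label = "--".join(sorted(tree.leaf_labels))

    def nll(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        lengths = {edges[0]: float(t)}
        for e in edges[1:]:
            lengths[e] = 0.0
        L = engine.class_site_likelihoods(kappa, omega, omega, lengths)
        return -float(site_w @ np.log(np.maximum(L, 1e-300)))

    res = minimize(
        nll, np.log([0.2, 2.0, 0.5]), method="L-BFGS-B",
        bounds=[_LOG_T_BOUNDS, _LOG_KAPPA_BOUNDS, _LOG_OMEGA_BOUNDS],
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    t, kappa, omega = (float(v) for v in np.exp(res.x))
    return {label: _branch_rates(label, t, omega, kappa, engine.pi, n_codons)}
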