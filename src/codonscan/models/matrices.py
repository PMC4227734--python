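"""Codon and nucleotide substitution rate matrices.

The codon process is the Goldman-Yang form: instantaneous rate from codon i
to j is zero unless the codons differ at exactly one position and neither is
a stop, and otherwise proportional to

    pi_j * kappa^[transition] * omega^[nonsynonymous]

Each generator is scaled so the expected number of substitutions per codon
per unit branch length is one, i.e. -sum_i pi_i q_ii = 1.  Because every
matrix here is reversible with respect to its stationary distribution, the
transition matrices P(t) = exp(Qt) are computed through a symmetric
eigendecomposition, which makes repeated evaluation at many branch lengths
cheap inside the optimisers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .. import genetics


@dataclass
class CodonModelParams:
    """kappa (transition/transversion rate ratio) and codon frequencies."""

    kappa: float
    pi: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.isfinite(self.kappa) or self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.pi.shape != (genetics.N_SENSE,):
            raise ValueError(f"pi must have length {genetics.N_SENSE}")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise ValueError("pi must be a probability vector over the sense codons")

    @classmethod
    def equal(cls, kappa: float = 2.0) -> "CodonModelParams":
        return cls(kappa=kappa, pi=genetics.equal_codon_frequencies())


def build_rate_matrix(params: CodonModelParams, omega: float, scale: bool = True) -> np.ndarray:
    """61x61 codon generator; single-step rule, scaled to mean rate 1."""
    if not np.isfinite(omega) or omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    pi = params.pi
    rates = pi[genetics.PAIR_COLS].copy()
    rates[genetics.PAIR_IS_TRANSITION] *= params.kappa
    rates[~genetics.PAIR_IS_SYNONYMOUS] *= omega
    Q = np.zeros((genetics.N_SENSE, genetics.N_SENSE))
    Q[genetics.PAIR_ROWS, genetics.PAIR_COLS] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def flux_split(params: CodonModelParams) -> tuple[float, float]:
    """(a, b): nonsynonymous and synonymous shares of the neutral flux.

    ``a + b = 1`` and for any omega the process with unit-scaled generator
    runs at relative rate ``g(omega) = omega * a + b`` compared to the
    neutral (omega = 1) process.  Branch lengths throughout the package are
    expressed on the neutral scale: a site class with ratio omega
    accumulates ``t * g(omega)`` substitutions per codon on a branch of
    length ``t``.
    """
    pi = params.pi
    w = pi[genetics.PAIR_ROWS] * pi[genetics.PAIR_COLS]
    w = np.where(genetics.PAIR_IS_TRANSITION, params.kappa * w, w)
    a = float(w[~genetics.PAIR_IS_SYNONYMOUS].sum())
    b = float(w[genetics.PAIR_IS_SYNONYMOUS].sum())
    tot = a + b
    return a / tot, b / tot


def relative_rate(params: CodonModelParams, omega: float) -> float:
    """Substitution rate of the omega class relative to the neutral class."""
    a, b = flux_split(params)
    return omega * a + b


def rate_decomposition(params: CodonModelParams, omega: float) -> tuple[float, float]:
    """(rho_N, rho_S): nonsynonymous / synonymous shares of the unit flux.

    Computed on the scaled generator, so rho_N + rho_S = 1.  The mutational
    site proportions used in the Ka/Ks decomposition are this quantity at
    omega = 1.
    """
    Q = build_rate_matrix(params, omega)
    flux = params.pi[genetics.PAIR_ROWS] * Q[genetics.PAIR_ROWS, genetics.PAIR_COLS]
    rho_n = float(flux[~genetics.PAIR_IS_SYNONYMOUS].sum())
    rho_s = float(flux[genetics.PAIR_IS_SYNONYMOUS].sum())
    return rho_n, rho_s


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for any generator; rejects negative t."""
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    if t == 0:
        return np.eye(Q.shape[0])
    return scipy.linalg.expm(Q * t)


@dataclass
class SpectralMatrix:
    """Eigendecomposition of a reversible generator for fast P(t).

    With D = diag(pi), the symmetrised matrix S = D^1/2 Q D^-1/2 has a real
    spectral decomposition S = V diag(lam) V'.  Then
    P(t) = D^-1/2 V diag(e^(lam t)) V' D^1/2.
    """

    Q: np.ndarray
    pi: np.ndarray
    _lam: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)  # D^-1/2 V
    _right: np.ndarray = field(init=False, repr=False)  # V' D^1/2

    def __post_init__(self):
        sqrt_pi = np.sqrt(self.pi)
        S = self.Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        S = 0.5 * (S + S.T)  # enforce exact symmetry against round-off
        lam, V = np.linalg.eigh(S)
        self._lam = lam
        self._left = V / sqrt_pi[:, None]
        self._right = V.T * sqrt_pi[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        P = (self._left * np.exp(self._lam * t)) @ self._right
        np.maximum(P, 0.0, out=P)
        return P


def codon_spectral(params: CodonModelParams, omega: float) -> SpectralMatrix:
    return SpectralMatrix(build_rate_matrix(params, omega), params.pi)


# -- nucleotide GTR ---------------------------------------------------------

def gtr_rate_matrix(exchangeabilities: np.ndarray, pi: np.ndarray, scale: bool = True) -> np.ndarray:
    """4x4 GTR generator, q_ij = s_ij pi_j, scaled to mean rate 1.

    ``exchangeabilities`` are the six symmetric rates in the order
    (AC, AG, AT, CG, CT, GT).
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if s.shape != (6,) or np.any(s < 0):
        raise ValueError("need 6 non-negative exchangeabilities")
    if pi.shape != (4,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must be a probability vector over ACGT")
    Q = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(s, idx):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def gtr_spectral(exchangeabilities: np.ndarray, pi: np.ndarray) -> SpectralMatrix:
    pi = np.asarray(pi, dtype=float)
    return SpectralMatrix(gtr_rate_matrix(exchangeabilities, pi), pi)
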