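"""Probabilistic Boolean network with per-edge discrete time delay.

The network over N genes is a signed adjacency A (a_ij in {-1, 0, 1},
zero diagonal: no self-regulation) plus a delay matrix Delta with
delta_ij in {0, ..., 5} interpolation units.  Gene i's input at a point
is H_i = sum_j a_ij s_j^{t - delta_ij}.  With no input (H = 0) the gene
keeps its previous state with probability sigma(alpha); with input it
turns on with probability exp(beta H) / (exp(beta H) + exp(-beta H)),
beta acting as an inverse-temperature noise parameter.

Priors: each adjacency row is empty with probability kappa, otherwise
its regulator count x follows a truncated exponential exp(-lambda x)
with support and signs uniform; delays are uniform on {0..5} for present
edges and spike-and-slab (mass 0.999 at 0) for absent ones, keeping the
parameter dimension fixed.  alpha ~ Gamma(1, 10), beta ~ Gamma(100, 100),
lambda ~ Gamma(490, 70) (shape-rate), kappa ~ Beta(6, 24).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import gamma as gamma_dist

from bbtd.integration import MAX_DELAY, SubtreeDataset

N_DELAYS = MAX_DELAY + 1

#: Spike-and-slab delay prior for absent edges: nearly all mass on 0.
SPIKE_AT_ZERO = 0.999
SLAB_PER_DELAY = 0.0002

#: Hyperprior shapes/rates (Gamma are shape-rate parametrized).
ALPHA_PRIOR = (1.0, 10.0)
BETA_PRIOR = (100.0, 100.0)
LAMBDA_PRIOR = (490.0, 70.0)
KAPPA_PRIOR = (6.0, 24.0)


@dataclass
class RegulatoryNetwork:
    """Signed adjacency plus delay matrix of a gene regulatory network."""

    A: np.ndarray  # (N, N) int8 in {-1, 0, 1}, zero diagonal
    Delta: np.ndarray  # (N, N) int8 in {0..5}

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.int8)
        self.Delta = np.asarray(self.Delta, dtype=np.int8)
        if self.A.shape != self.Delta.shape or self.A.ndim != 2:
            raise ValueError("A and Delta must be square and conformable")
        if self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("self-regulation is not modeled: diag(A) must be 0")
        if not np.isin(self.A, (-1, 0, 1)).all():
            raise ValueError("A entries must be in {-1, 0, 1}")
        if not np.isin(self.Delta, np.arange(N_DELAYS)).all():
            raise ValueError(f"Delta entries must be in 0..{MAX_DELAY}")

    @property
    def n_genes(self) -> int:
        return self.A.shape[0]

    def x(self) -> np.ndarray:
        """Per-row regulator counts x_i."""
        return (self.A != 0).sum(axis=1)


@dataclass
class ModelParams:
    """State-persistence strength alpha and inverse-noise beta."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")


@dataclass
class HyperParams:
    """Sparsity hyperparameters of the row prior."""

    lam: float  # decay of the regulator-count distribution
    kappa: float  # prior mass of an empty row

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lambda must be positive")
        if not 0 < self.kappa < 1:
            raise ValueError("kappa must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def input_signal(a_row: np.ndarray, d_row: np.ndarray, lagged: np.ndarray) -> int:
    """Signed input H of one gene: sum_j a_ij * s_j at lag delta_ij.

    ``lagged[j, m]`` is regulator j's state m units back along the
    lineage path.
    """
    a_row = np.asarray(a_row)
    d_row = np.asarray(d_row)
    lagged = np.asarray(lagged)
    sel = lagged[np.arange(lagged.shape[0]), d_row]
    return int(np.dot(a_row, sel))


def persistence_prob(alpha: float) -> float:
    """Probability of keeping the previous state when the input is zero."""
    return 1.0 / (1.0 + np.exp(-alpha))


def transition_prob(s: int, H: int, beta: float) -> float:
    """Probability of state ``s`` given nonzero input ``H``."""
    bh = beta * H
    return float(np.exp((2 * s - 1) * bh - np.logaddexp(bh, -bh)))


# ---------------------------------------------------------------------------
# Fast likelihood workspace
# ---------------------------------------------------------------------------

class LikelihoodWorkspace:
    """Precomputed lag lookups for repeated likelihood evaluation.

    Flattens the dataset's lineage structure into, per gene, the vector
    of its states at the usable points (those whose 5-step history
    resolves) and the six lagged state vectors used as regressors, so
    that per-gene log-likelihood terms reduce to vector arithmetic.
    """

    def __init__(self, dataset: SubtreeDataset):
        if dataset.missing.any():
            raise ValueError("resolve missing values before likelihood evaluation")
        lag = dataset.lag_indices(MAX_DELAY)
        self.usable = np.flatnonzero(lag[MAX_DELAY] >= 0)
        if self.usable.size == 0:
            raise ValueError(
                "no usable points: every lineage path is shorter than "
                f"{MAX_DELAY + 1} interpolations"
            )
        idx = lag[:, self.usable]  # (6, Tu)
        # lagstate[j, m, t] = state of gene j, m units before usable point t
        self.lagstate = dataset.states[:, idx].astype(np.float64)
        self.s_now = dataset.states[:, self.usable].astype(np.float64)
        self.sign_now = 2.0 * self.s_now - 1.0
        self.same_as_prev = dataset.states[:, self.usable] == dataset.states[:, idx[1]]
        self.n_genes = dataset.n_genes
        self.n_usable = self.usable.size

    def input_matrix(self, A: np.ndarray, Delta: np.ndarray) -> np.ndarray:
        """(N, Tu) matrix of inputs H_i at every usable point."""
        N = self.n_genes
        sel = self.lagstate[np.arange(N)[None, :], Delta, :]  # (N, N, Tu)
        return np.einsum("ij,ijt->it", A.astype(np.float64), sel)

    def gene_loglik_terms(self, i: int, H: np.ndarray, alpha: float, beta: float) -> np.ndarray:
        """Log transition probabilities of gene i for input rows ``H``.

        ``H`` may carry leading axes (variant enumeration); the usable-
        point axis is last.  Zero-input points use the persistence law.
        """
        lp = -np.log1p(np.exp(-alpha))  # log sigma(alpha)
        lq = -alpha + lp  # log (1 - sigma(alpha))
        bh = beta * H
        ll = self.sign_now[i] * bh - np.logaddexp(bh, -bh)
        persist = np.where(self.same_as_prev[i], lp, lq)
        return np.where(H == 0, persist, ll)

    def total_loglik(self, H: np.ndarray, alpha: float, beta: float) -> float:
        lp = -np.log1p(np.exp(-alpha))
        lq = -alpha + lp
        bh = beta * H
        ll = self.sign_now * bh - np.logaddexp(bh, -bh)
        persist = np.where(self.same_as_prev, lp, lq)
        return float(np.where(H == 0, persist, ll).sum())


def log_likelihood(
    dataset: SubtreeDataset,
    A: np.ndarray,
    Delta: np.ndarray,
    alpha: float,
    beta: float,
    workspace: LikelihoodWorkspace | None = None,
) -> float:
    """Log-likelihood of the binary subtree dataset under (A, Delta).

    Sums log transition probabilities over every gene and every point
    whose five-unit lag history resolves along its lineage path
    (daughter cells read back into their parent's terminal points).
    """
    ws = workspace or LikelihoodWorkspace(dataset)
    H = ws.input_matrix(np.asarray(A), np.asarray(Delta))
    return ws.total_loglik(H, alpha, beta)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def normalizing_c(lam: float, N: int) -> float:
    """Normalizer of the truncated exponential over x in {1, .., N-1}."""
    if N < 2:
        raise ValueError("need at least 2 genes")
    x = np.arange(1, N)
    return float(1.0 / np.sum(np.exp(-lam * x)))


def _log_comb(n: int, k: np.ndarray | int) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def log_prior_row_count(x: int, lam: float, kappa: float, N: int) -> float:
    """Log prior of one adjacency row with x nonzero entries.

    The prior factorizes as: empty with probability kappa; otherwise a
    truncated-exponential count, a uniform choice of which of the
    C(N-1, x) regulator sets, and independent uniform signs (2^-x).
    """
    if x == 0:
        return float(np.log(kappa))
    return float(
        np.log1p(-kappa)
        + np.log(normalizing_c(lam, N))
        - lam * x
        - _log_comb(N - 1, x)
        - x * np.log(2.0)
    )


def log_prior_row(a_row: np.ndarray, lam: float, kappa: float) -> float:
    """Log prior of a full adjacency row (its own entry excluded)."""
    a_row = np.asarray(a_row)
    N = a_row.size
    return log_prior_row_count(int(np.count_nonzero(a_row)), lam, kappa, N)


_LOG_UNIFORM_DELAY = float(np.log(1.0 / N_DELAYS))
_LOG_SPIKE = float(np.log(SPIKE_AT_ZERO))
_LOG_SLAB = float(np.log(SLAB_PER_DELAY))


def log_prior_delay(delta: int, a: int) -> float:
    """Log prior of one delay entry given its edge indicator."""
    if not 0 <= delta <= MAX_DELAY:
        return -np.inf
    if a != 0:
        return _LOG_UNIFORM_DELAY
    return _LOG_SPIKE if delta == 0 else _LOG_SLAB


def log_hyperprior(alpha: float, beta: float, lam: float, kappa: float) -> float:
    """Log density of the four continuous parameters under their priors."""
    return float(
        gamma_dist.logpdf(alpha, ALPHA_PRIOR[0], scale=1.0 / ALPHA_PRIOR[1])
        + gamma_dist.logpdf(beta, BETA_PRIOR[0], scale=1.0 / BETA_PRIOR[1])
        + gamma_dist.logpdf(lam, LAMBDA_PRIOR[0], scale=1.0 / LAMBDA_PRIOR[1])
        + beta_dist.logpdf(kappa, KAPPA_PRIOR[0], KAPPA_PRIOR[1])
    )


def log_network_prior(
    A: np.ndarray, Delta: np.ndarray, lam: float, kappa: float
) -> float:
    """Joint log prior of (A, Delta): rows times conditional delays."""
    A = np.asarray(A)
    Delta = np.asarray(Delta)
    N = A.shape[0]
    total = 0.0
    for i in range(N):
        total += log_prior_row_count(int(np.count_nonzero(A[i])), lam, kappa, N)
    off = ~np.eye(N, dtype=bool)
    present = (A != 0) & off
    absent = (A == 0) & off
    total += present.sum() * _LOG_UNIFORM_DELAY
    total += (absent & (Delta == 0)).sum() * _LOG_SPIKE
    total += (absent & (Delta != 0)).sum() * _LOG_SLAB
    return float(total)


def log_posterior(
    dataset: SubtreeDataset,
    A: np.ndarray,
    Delta: np.ndarray,
    alpha: float,
    beta: float,
    lam: float,
    kappa: float,
    workspace: LikelihoodWorkspace | None = None,
) -> float:
    """Unnormalized log posterior of the full parameter set."""
    return (
        log_likelihood(dataset, A, Delta, alpha, beta, workspace)
        + log_network_prior(A, Delta, lam, kappa)
        + log_hyperprior(alpha, beta, lam, kappa)
    )
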