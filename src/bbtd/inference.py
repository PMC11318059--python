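"""MCMC over the network, delays and continuous parameters.

Each retained (edge, delay) pair is Gibbs-updated jointly from its
exact 18-state conditional (sign in {-1, 0, 1} x delay in {0..5}), so
the sampler cannot stick in the spike of an absent edge.  The four
continuous parameters move by Metropolis-Hastings random walks on the
log scale (alpha, beta, lambda) or logit scale (kappa), with Jacobian-
corrected acceptance.  Chains are initialized at the empty network and
prior means; the first half of every chain is discarded as burn-in and
the maximum-a-posteriori estimate is the retained sample of highest
joint log posterior across chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bbtd.integration import MAX_DELAY, SubtreeDataset
from bbtd.model import (
    ALPHA_PRIOR,
    BETA_PRIOR,
    KAPPA_PRIOR,
    LAMBDA_PRIOR,
    HyperParams,
    LikelihoodWorkspace,
    ModelParams,
    RegulatoryNetwork,
    _LOG_SLAB,
    _LOG_SPIKE,
    _LOG_UNIFORM_DELAY,
    log_hyperprior,
    log_network_prior,
    log_prior_row_count,
)
from bbtd.prescreen import PrescreenMask

N_DELAYS = MAX_DELAY + 1
N_EDGE_STATES = 3 * N_DELAYS  # sign {0,+1,-1} x delay {0..5}

#: Enumeration order of the joint (sign, delay) edge states.
EDGE_STATES: list[tuple[int, int]] = (
    [(0, d) for d in range(N_DELAYS)]
    + [(1, d) for d in range(N_DELAYS)]
    + [(-1, d) for d in range(N_DELAYS)]
)


@dataclass
class MCMCConfig:
    """Chain count, length and proposal scales of the sampler."""

    n_iterations: int = 10_000
    n_chains: int = 3
    proposal_scales: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.2, "beta": 0.2, "lam": 0.2, "kappa": 0.2}
    )
    adapt_during_burnin: bool = False
    seed: int = 0


@dataclass
class SamplerState:
    A: np.ndarray
    Delta: np.ndarray
    alpha: float
    beta: float
    lam: float
    kappa: float

    def copy(self) -> "SamplerState":
        return SamplerState(
            self.A.copy(), self.Delta.copy(),
            self.alpha, self.beta, self.lam, self.kappa,
        )


@dataclass
class ChainTrace:
    A: np.ndarray  # (n_iter, N, N) int8
    Delta: np.ndarray  # (n_iter, N, N) int8
    alpha: np.ndarray
    beta: np.ndarray
    lam: np.ndarray
    kappa: np.ndarray
    log_posterior: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.alpha.size


@dataclass
class PosteriorSamples:
    """Per-chain traces with the burn-in boundary (first half)."""

    chains: list[ChainTrace]
    config: MCMCConfig

    def burn_in(self, chain: int) -> int:
        """Index of the first retained sample (half the chain, rounded down)."""
        return len(self.chains[chain]) // 2


@dataclass
class MAPEstimate:
    network: RegulatoryNetwork
    params: ModelParams
    hyper: HyperParams
    log_posterior: float
    chain: int
    iteration: int


def _initial_state(n_genes: int) -> SamplerState:
    return SamplerState(
        A=np.zeros((n_genes, n_genes), dtype=np.int8),
        Delta=np.zeros((n_genes, n_genes), dtype=np.int8),
        alpha=ALPHA_PRIOR[0] / ALPHA_PRIOR[1],
        beta=BETA_PRIOR[0] / BETA_PRIOR[1],
        lam=LAMBDA_PRIOR[0] / LAMBDA_PRIOR[1],
        kappa=KAPPA_PRIOR[0] / (KAPPA_PRIOR[0] + KAPPA_PRIOR[1]),
    )


class MCMCSampler:
    """One chain of the Gibbs / Metropolis-Hastings sampler.

    Maintains the input matrix H and the current total log-likelihood
    incrementally so that an edge update costs one 13-row likelihood
    enumeration over the usable points.
    """

    def __init__(
        self,
        dataset: SubtreeDataset,
        mask: PrescreenMask,
        rng: np.random.Generator,
        config: MCMCConfig | None = None,
        init: SamplerState | None = None,
        workspace: LikelihoodWorkspace | None = None,
    ):
        self.config = config or MCMCConfig()
        self.rng = rng
        self.ws = workspace or LikelihoodWorkspace(dataset)
        self.mask = mask
        self.N = dataset.n_genes
        self.pairs = [tuple(p) for p in mask.retained_pairs()]
        self.state = init.copy() if init is not None else _initial_state(self.N)
        self._refresh_caches()
        self.scales = dict(self.config.proposal_scales)

    # -- cached quantities -------------------------------------------------
    def _refresh_caches(self) -> None:
        self.H = self.ws.input_matrix(self.state.A, self.state.Delta)
        self.loglik = self.ws.total_loglik(self.H, self.state.alpha, self.state.beta)

    def set_state(self, state: SamplerState) -> None:
        self.state = state.copy()
        self._refresh_caches()

    def log_posterior(self) -> float:
        s = self.state
        return (
            self.loglik
            + log_network_prior(s.A, s.Delta, s.lam, s.kappa)
            + log_hyperprior(s.alpha, s.beta, s.lam, s.kappa)
        )

    # -- Gibbs -------------------------------------------------------------
    def edge_conditional(self, i: int, j: int) -> np.ndarray:
        """Normalized conditional over the 18 joint (sign, delay) states."""
        s = self.state
        L = self.ws.lagstate[j]  # (6, Tu)
        a_cur = int(s.A[i, j])
        H0 = self.H[i] - a_cur * L[s.Delta[i, j]] if a_cur else self.H[i]
        variants = np.empty((2 * N_DELAYS + 1, H0.size))
        variants[0] = H0
        variants[1 : N_DELAYS + 1] = H0[None, :] + L
        variants[N_DELAYS + 1 :] = H0[None, :] - L
        ll = self.ws.gene_loglik_terms(i, variants, s.alpha, s.beta).sum(axis=1)
        x_wo = int(np.count_nonzero(s.A[i])) - (1 if a_cur else 0)
        lp_absent = log_prior_row_count(x_wo, s.lam, s.kappa, self.N)
        lp_present = log_prior_row_count(x_wo + 1, s.lam, s.kappa, self.N)
        logw = np.empty(N_EDGE_STATES)
        logw[0] = ll[0] + lp_absent + _LOG_SPIKE
        logw[1:N_DELAYS] = ll[0] + lp_absent + _LOG_SLAB
        logw[N_DELAYS : 2 * N_DELAYS] = ll[1 : N_DELAYS + 1] + lp_present + _LOG_UNIFORM_DELAY
        logw[2 * N_DELAYS :] = ll[N_DELAYS + 1 :] + lp_present + _LOG_UNIFORM_DELAY
        logw -= logw.max()
        w = np.exp(logw)
        return w / w.sum()

    def _apply_edge(self, i: int, j: int, a_new: int, d_new: int) -> None:
        s = self.state
        L = self.ws.lagstate[j]
        a_cur, d_cur = int(s.A[i, j]), int(s.Delta[i, j])
        if (a_new, d_new) == (a_cur, d_cur):
            return
        dH = 0.0
        if a_cur:
            dH = -a_cur * L[d_cur]
        if a_new:
            dH = dH + a_new * L[d_new]
        if a_cur or a_new:
            old_terms = self.ws.gene_loglik_terms(i, self.H[i], s.alpha, s.beta).sum()
            self.H[i] = self.H[i] + dH
            new_terms = self.ws.gene_loglik_terms(i, self.H[i], s.alpha, s.beta).sum()
            self.loglik += new_terms - old_terms
        s.A[i, j] = a_new
        s.Delta[i, j] = d_new

    def gibbs_sweep(self) -> None:
        """Update every retained (a_ij, delta_ij) once, in scan order."""
        for i, j in self.pairs:
            probs = self.edge_conditional(i, j)
            idx = int(self.rng.choice(N_EDGE_STATES, p=probs))
            a_new, d_new = EDGE_STATES[idx]
            self._apply_edge(i, j, a_new, d_new)

    # -- Metropolis-Hastings ----------------------------------------------
    def _row_prior_sum(self, lam: float, kappa: float) -> float:
        xs = (self.state.A != 0).sum(axis=1)
        return float(
            sum(log_prior_row_count(int(x), lam, kappa, self.N) for x in xs)
        )

    def mh_update(self, name: str) -> bool:
        """One M-H step on alpha, beta, lam (log walk) or kappa (logit walk)."""
        s = self.state
        scale = self.scales[name]
        eps = self.rng.normal(0.0, scale)
        from scipy.stats import beta as beta_dist, gamma as gamma_dist

        if name in ("alpha", "beta"):
            cur = getattr(s, name)
            new = cur * np.exp(eps)
            shape, rate = ALPHA_PRIOR if name == "alpha" else BETA_PRIOR
            if name == "alpha":
                new_ll = self.ws.total_loglik(self.H, new, s.beta)
            else:
                new_ll = self.ws.total_loglik(self.H, s.alpha, new)
            logr = (
                new_ll - self.loglik
                + gamma_dist.logpdf(new, shape, scale=1.0 / rate)
                - gamma_dist.logpdf(cur, shape, scale=1.0 / rate)
                + np.log(new) - np.log(cur)
            )
            if np.log(self.rng.random()) < logr:
                setattr(s, name, float(new))
                self.loglik = float(new_ll)
                return True
            return False
        if name == "lam":
            cur, new = s.lam, s.lam * np.exp(eps)
            logr = (
                self._row_prior_sum(new, s.kappa)
                - self._row_prior_sum(cur, s.kappa)
                + gamma_dist.logpdf(new, LAMBDA_PRIOR[0], scale=1.0 / LAMBDA_PRIOR[1])
                - gamma_dist.logpdf(cur, LAMBDA_PRIOR[0], scale=1.0 / LAMBDA_PRIOR[1])
                + np.log(new) - np.log(cur)
            )
            if np.log(self.rng.random()) < logr:
                s.lam = float(new)
                return True
            return False
        if name == "kappa":
            cur = s.kappa
            logit = np.log(cur / (1 - cur)) + eps
            new = 1.0 / (1.0 + np.exp(-logit))
            logr = (
                self._row_prior_sum(s.lam, new)
                - self._row_prior_sum(s.lam, cur)
                + beta_dist.logpdf(new, *KAPPA_PRIOR)
                - beta_dist.logpdf(cur, *KAPPA_PRIOR)
                + np.log(new * (1 - new)) - np.log(cur * (1 - cur))
            )
            if np.log(self.rng.random()) < logr:
                s.kappa = float(new)
                return True
            return False
        raise ValueError(f"unknown parameter {name!r}")

    def step(self) -> None:
        """One full iteration: Gibbs sweep plus one M-H move per parameter."""
        self.gibbs_sweep()
        for name in ("alpha", "beta", "lam", "kappa"):
            self.mh_update(name)


def run_mcmc(
    dataset: SubtreeDataset,
    mask: PrescreenMask,
    config: MCMCConfig | None = None,
    init: SamplerState | None = None,
) -> PosteriorSamples:
    """Run independent chains and record full traces.

    Chain c uses the child seed spawned from ``config.seed`` so chains
    are independently reproducible.
    """
    config = config or MCMCConfig()
    ws = LikelihoodWorkspace(dataset)
    N = dataset.n_genes
    chains: list[ChainTrace] = []
    accept_window = 50
    for c in range(config.n_chains):
        chain_seed = np.random.SeedSequence(config.seed).spawn(config.n_chains)[c]
        rng = np.random.default_rng(chain_seed)
        sampler = MCMCSampler(dataset, mask, rng, config, init=init, workspace=ws)
        n = config.n_iterations
        tr_A = np.empty((n, N, N), dtype=np.int8)
        tr_D = np.empty((n, N, N), dtype=np.int8)
        scal = {k: np.empty(n) for k in ("alpha", "beta", "lam", "kappa")}
        logpost = np.empty(n)
        acc = {k: 0 for k in ("alpha", "beta", "lam", "kappa")}
        for it in range(n):
            sampler.gibbs_sweep()
            for name in ("alpha", "beta", "lam", "kappa"):
                acc[name] += sampler.mh_update(name)
            if (
                config.adapt_during_burnin
                and it < n // 2
                and (it + 1) % accept_window == 0
            ):
                for name in acc:
                    rate = acc[name] / accept_window
                    sampler.scales[name] *= float(np.exp(rate - 0.44))
                    acc[name] = 0
            tr_A[it] = sampler.state.A
            tr_D[it] = sampler.state.Delta
            for k in scal:
                scal[k][it] = getattr(sampler.state, k)
            logpost[it] = sampler.log_posterior()
        chains.append(
            ChainTrace(
                A=tr_A, Delta=tr_D,
                alpha=scal["alpha"], beta=scal["beta"],
                lam=scal["lam"], kappa=scal["kappa"],
                log_posterior=logpost,
                seed=int(chain_seed.generate_state(1)[0] % 2**31),
            )
        )
    return PosteriorSamples(chains=chains, config=config)


def map_estimate(samples: PosteriorSamples) -> MAPEstimate:
    """Joint-argmax MAP over post-burn-in samples of all chains.

    Discards the first half of every chain (retaining ceil(n/2)
    samples) and returns the sampled state with the highest recorded
    joint log posterior.
    """
    best: tuple[float, int, int] | None = None
    for c, chain in enumerate(samples.chains):
        b = samples.burn_in(c)
        idx = int(np.argmax(chain.log_posterior[b:])) + b
        lp = float(chain.log_posterior[idx])
        if best is None or lp > best[0]:
            best = (lp, c, idx)
    if best is None:
        raise ValueError("no chains")
    lp, c, idx = best
    chain = samples.chains[c]
    return MAPEstimate(
        network=RegulatoryNetwork(A=chain.A[idx], Delta=chain.Delta[idx]),
        params=ModelParams(alpha=float(chain.alpha[idx]), beta=float(chain.beta[idx])),
        hyper=HyperParams(lam=float(chain.lam[idx]), kappa=float(chain.kappa[idx])),
        log_posterior=lp,
        chain=c,
        iteration=idx,
    )
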