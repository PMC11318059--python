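"""Shared sampler test utilities and the edge-conditional oracle."""

import numpy as np

from bbtd.inference import EDGE_STATES
from bbtd.model import log_posterior
from bbtd.prescreen import PrescreenMask


def full_mask(n: int) -> PrescreenMask:
    """Retention mask keeping every off-diagonal candidate edge."""
    tilde = np.ones((n, n), np.int8)
    np.fill_diagonal(tilde, 0)
    return PrescreenMask(tilde_A=tilde, min_p=np.zeros((n, n)), theta=1.0)


def brute_force_edge_conditional(ds, state, i, j):
    """Normalize exp(log posterior) over the 18 joint (a, delta) states.

    Deliberately evaluates the *full* joint posterior for every variant;
    terms not involving (a_ij, delta_ij) cancel in the normalization.
    """
    logps = []
    for a, d in EDGE_STATES:
        A = state.A.copy()
        D = state.Delta.copy()
        A[i, j], D[i, j] = a, d
        logps.append(
            log_posterior(ds, A, D, state.alpha, state.beta, state.lam, state.kappa)
        )
    logps = np.array(logps)
    w = np.exp(logps - logps.max())
    return w / w.sum()
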