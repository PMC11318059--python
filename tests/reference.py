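"""Slow, independent reference implementations used as test oracles.

These deliberately follow the model definitions term by term with plain
Python loops, sharing no code with the package's vectorized paths.
"""

import itertools
import math

import numpy as np


def ref_lag_chain(prev, p, m):
    """m-step predecessor of point p, or None."""
    for _ in range(m):
        if p < 0:
            return None
        p = prev[p]
    return None if p < 0 else int(p)


def ref_log_likelihood(dataset, A, Delta, alpha, beta):
    """Direct per-point, per-gene evaluation of the transition laws."""
    prev = dataset.prev
    states = dataset.states
    N, T = states.shape
    total = 0.0
    for p in range(T):
        if ref_lag_chain(prev, p, 5) is None:
            continue
        for i in range(N):
            H = 0
            for j in range(N):
                if A[i, j] != 0:
                    q = ref_lag_chain(prev, p, int(Delta[i, j]))
                    H += int(A[i, j]) * int(states[j, q])
            s = int(states[i, p])
            if H == 0:
                s_prev = int(states[i, prev[p]])
                pk = 1.0 / (1.0 + math.exp(-alpha))
                total += math.log(pk if s == s_prev else 1.0 - pk)
            else:
                num = math.exp(beta * (2 * s - 1) * H)
                den = math.exp(beta * H) + math.exp(-beta * H)
                total += math.log(num / den)
    return total


def ref_row_prior(row, lam, kappa):
    """Direct evaluation of the sparse row prior for a full row."""
    N = len(row)
    x = sum(1 for a in row if a != 0)
    if x == 0:
        return kappa
    c = 1.0 / sum(math.exp(-lam * k) for k in range(1, N))
    return (
        (1.0 - kappa)
        * c
        * math.exp(-lam * x)
        / math.comb(N - 1, x)
        / 2**x
    )


def enumerate_rows(N, i):
    """All 3^(N-1) signed rows for gene i (diagonal forced to 0)."""
    others = [j for j in range(N) if j != i]
    for combo in itertools.product((-1, 0, 1), repeat=N - 1):
        row = np.zeros(N, dtype=np.int8)
        for j, a in zip(others, combo):
            row[j] = a
        yield row


def ref_fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-7)))
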