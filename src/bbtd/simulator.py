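"""Synthetic tree-shaped binary datasets drawn from the generative model.

Ground-truth networks and parameters are drawn from the model's own
priors; states are then simulated forward along a balanced binary cell
lineage, each daughter inheriting the mother's state history, matching
the gene/cell/interpolation counts of the five real subtree datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from bbtd.integration import MAX_DELAY, SubtreeDataset, layout_points
from bbtd.lineage_io import RawEmbryoFile
from bbtd.model import (
    ALPHA_PRIOR,
    BETA_PRIOR,
    KAPPA_PRIOR,
    LAMBDA_PRIOR,
    SLAB_PER_DELAY,
    SPIKE_AT_ZERO,
    HyperParams,
    ModelParams,
    RegulatoryNetwork,
    persistence_prob,
)

#: Gene, cell and per-cell interpolation counts of the five real
#: subtree datasets.
SUBTREE_DIMENSIONS: dict[str, tuple[int, int, int]] = {
    "AB": (27, 112, 24),
    "C": (30, 51, 20),
    "D": (20, 12, 28),
    "E": (40, 26, 16),
    "MS": (29, 80, 22),
}


@dataclass
class SimConfig:
    """Dimensions and rules of one synthetic dataset.

    ``inters_per_cell`` must exceed the maximum delay so that a cell can
    carry a full lag history; the first five indices of each root cell
    are initialized i.i.d. Bernoulli(1/2) per gene (they never enter the
    likelihood, which starts once the five-lag history resolves).
    """

    n_genes: int
    n_cells: int
    inters_per_cell: int
    subtree_label: str | None = None
    history_init: str = "bernoulli_half"

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.inters_per_cell < MAX_DELAY + 1:
            raise ValueError(
                f"inters_per_cell must be >= {MAX_DELAY + 1} (max delay {MAX_DELAY})"
            )
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


def make_subtree_config(subtree_label: str) -> SimConfig:
    """Configuration matching one real subtree's dimensions."""
    try:
        n_genes, n_cells, inters = SUBTREE_DIMENSIONS[subtree_label]
    except KeyError:
        raise ValueError(f"unknown subtree label {subtree_label!r}") from None
    return SimConfig(
        n_genes=n_genes,
        n_cells=n_cells,
        inters_per_cell=inters,
        subtree_label=subtree_label,
    )


def balanced_tree_cells(n_cells: int, root: str = "S") -> dict[str, str | None]:
    """Parent map of a balanced binary tree grown breadth-first.

    Cell names extend the root's name with 'a'/'p' (anterior/posterior),
    Sulston style.
    """
    parents: dict[str, str | None] = {root: None}
    frontier = [root]
    while len(parents) < n_cells:
        nxt: list[str] = []
        for name in frontier:
            for suffix in ("a", "p"):
                if len(parents) >= n_cells:
                    break
                child = name + suffix
                parents[child] = name
                nxt.append(child)
        frontier = nxt
    return parents


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def _draw_row_count(n_genes: int, lam: float, kappa: float, rng: np.random.Generator) -> int:
    if rng.random() < kappa:
        return 0
    x = np.arange(1, n_genes)
    w = np.exp(-lam * x)
    return int(rng.choice(x, p=w / w.sum()))


def draw_truth(
    n_genes: int, seed: int | np.random.Generator
) -> tuple[RegulatoryNetwork, ModelParams, HyperParams]:
    """Draw a ground-truth network and parameters from the priors.

    Two-stage row draw: empty with probability kappa, otherwise the
    regulator count from the truncated exponential, the regulator set
    uniform among subsets, signs uniform.  Delays are uniform on 0..5
    for present edges and spike-and-slab for absent ones.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kappa = float(rng.beta(KAPPA_PRIOR[0], KAPPA_PRIOR[1]))
    lam = float(rng.gamma(LAMBDA_PRIOR[0], 1.0 / LAMBDA_PRIOR[1]))
    alpha = float(rng.gamma(ALPHA_PRIOR[0], 1.0 / ALPHA_PRIOR[1]))
    beta = float(rng.gamma(BETA_PRIOR[0], 1.0 / BETA_PRIOR[1]))
    N = n_genes
    A = np.zeros((N, N), dtype=np.int8)
    Delta = np.zeros((N, N), dtype=np.int8)
    for i in range(N):
        x = _draw_row_count(N, lam, kappa, rng)
        if x:
            others = np.delete(np.arange(N), i)
            regs = rng.choice(others, size=x, replace=False)
            A[i, regs] = rng.choice([-1, 1], size=x)
    slab = np.concatenate(([SPIKE_AT_ZERO], np.full(MAX_DELAY, SLAB_PER_DELAY)))
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            if A[i, j] != 0:
                Delta[i, j] = rng.integers(0, MAX_DELAY + 1)
            else:
                Delta[i, j] = rng.choice(MAX_DELAY + 1, p=slab)
    return (
        RegulatoryNetwork(A=A, Delta=Delta),
        ModelParams(alpha=alpha, beta=beta),
        HyperParams(lam=lam, kappa=kappa),
    )


# ---------------------------------------------------------------------------
# Forward simulation
# ---------------------------------------------------------------------------

def _update_order(A: np.ndarray, Delta: np.ndarray) -> np.ndarray | None:
    """Topological gene order under instantaneous (delay-0) edges.

    Sequential generation within a time slice reproduces the model's
    conditional factorization exactly when the delay-0 subgraph is
    acyclic; returns None when it is not.
    """
    N = A.shape[0]
    adj = (A != 0) & (Delta == 0)
    indeg = adj.sum(axis=1)
    order: list[int] = []
    ready = [i for i in range(N) if indeg[i] == 0]
    while ready:
        i = ready.pop()
        order.append(i)
        for k in np.flatnonzero(adj[:, i]):
            indeg[k] -= 1
            if indeg[k] == 0:
                ready.append(int(k))
    if len(order) < N:
        return None
    return np.asarray(order)


def simulate_dataset(
    truth: tuple[RegulatoryNetwork, ModelParams, HyperParams] | RegulatoryNetwork,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    params: ModelParams | None = None,
) -> SubtreeDataset:
    """Simulate a binary subtree dataset forward along the lineage.

    Each gene's state at a point is drawn from the persistence law when
    its input H is zero and from the noisy-threshold law otherwise,
    with lags resolved through the lineage-path predecessor chain (both
    daughters read the mother's terminal history).  Genes within a time
    slice are generated in topological order of the delay-0 subgraph
    when it is acyclic — in which case the scheme matches the model
    exactly — and in a seeded random permutation otherwise, reading a
    not-yet-updated delay-0 regulator at its previous index.
    """
    if isinstance(truth, RegulatoryNetwork):
        network = truth
        if params is None:
            raise ValueError("params required when truth is a bare network")
    else:
        network, params, _ = truth
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A, Delta = network.A, network.Delta
    N = config.n_genes
    if A.shape[0] != N:
        raise ValueError("network size does not match config.n_genes")
    root = config.subtree_label or "S"
    parents = balanced_tree_cells(config.n_cells, root=root)
    cell_of_point, prev, _ = layout_points(
        list(parents), parents, config.inters_per_cell
    )
    T = prev.size
    states = np.zeros((N, T), dtype=np.int8)

    regs = [
        [(int(j), int(A[i, j]), int(Delta[i, j])) for j in np.flatnonzero(A[i])]
        for i in range(N)
    ]
    topo = _update_order(A, Delta)
    p_keep = persistence_prob(params.alpha)
    beta = params.beta

    # ancestor chain per point, up to MAX_DELAY back
    anc = np.empty((MAX_DELAY + 1, T), dtype=np.int64)
    anc[0] = np.arange(T)
    for m in range(1, MAX_DELAY + 1):
        row = anc[m - 1]
        anc[m] = np.where(row >= 0, prev[row], -1)

    for p in range(T):
        u = rng.random(N)
        if anc[MAX_DELAY, p] < 0:  # incomplete history: root-cell warm-up
            states[:, p] = (u < 0.5).astype(np.int8)
            continue
        order = topo if topo is not None else rng.permutation(N)
        done = np.zeros(N, dtype=bool)
        prev_p = prev[p]
        for i in order:
            H = 0
            for j, a, d in regs[i]:
                if d == 0:
                    sj = states[j, p] if done[j] else states[j, prev_p]
                else:
                    sj = states[j, anc[d, p]]
                H += a * sj
            if H == 0:
                keep = u[i] < p_keep
                s = states[i, prev_p] if keep else 1 - states[i, prev_p]
            else:
                p1 = 1.0 / (1.0 + np.exp(-2.0 * beta * H))
                s = 1 if u[i] < p1 else 0
            states[i, p] = s
            done[i] = True

    return SubtreeDataset(
        states=states,
        missing=np.zeros((N, T), dtype=bool),
        gene_names=[f"g{i}" for i in range(N)],
        cell_of_point=cell_of_point,
        prev=prev,
        subtree_label=config.subtree_label,
    )


def save_truth(
    path: str | Path,
    network: RegulatoryNetwork,
    params: ModelParams,
    hyper: HyperParams,
) -> None:
    """Write the ground truth of a simulation as JSON."""
    payload = {
        "A": network.A.tolist(),
        "Delta": network.Delta.tolist(),
        "alpha": params.alpha,
        "beta": params.beta,
        "lambda": hyper.lam,
        "kappa": hyper.kappa,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Raw-fluorescence fixture generator (integration-module testing only)
# ---------------------------------------------------------------------------

def make_raw_fixture(
    gene_names: list[str],
    n_copies: int = 2,
    subtree_label: str = "E",
    depth: int = 2,
    points_range: tuple[int, int] = (8, 14),
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[RawEmbryoFile]:
    """Small synthetic raw-fluorescence files with misaligned copies.

    Emulates the real data's structure: per-copy cell lifetimes (point
    counts) differ, intensities are monotone cumulative sums of binary
    rate templates plus Gaussian noise.  Intended for exercising the
    integration pipeline, not for modeling fluorescence physics.
    """
    import pandas as pd

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = subtree_label + "a"  # e.g. "Ea"
    cells = [root]
    frontier = [root]
    for _ in range(depth):
        nxt = []
        for c in frontier:
            nxt.extend([c + "l", c + "r"])
        cells.extend(nxt)
        frontier = nxt
    files: list[RawEmbryoFile] = []
    for gene in gene_names:
        template = {c: rng.choice([0.2, 2.0]) for c in cells}
        for _copy in range(n_copies):
            rows = []
            for cell in cells:
                n_pts = int(rng.integers(*points_range))
                rates = template[cell] + rng.normal(0, noise_sd, size=n_pts)
                intensity = 50.0 + np.cumsum(np.abs(rates))
                for t, v in enumerate(intensity, start=1):
                    rows.append((cell, t, float(v)))
            files.append(
                RawEmbryoFile(
                    gene_name=gene,
                    records=pd.DataFrame(
                        rows, columns=["cell", "time", "intensity"]
                    ),
                )
            )
    return files
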