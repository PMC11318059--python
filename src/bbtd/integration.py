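"""Four-step integration of non-pairwise lineage-tree fluorescence data.

Each embryo file records one labeled gene, and the lifetime of a given
cell differs between embryos, so series from different files cannot be
aligned on absolute time.  The pipeline makes them pairwise:

1. normalize every cell's lifetime to [0, 1];
2. difference the intensities (expression rates) and cubic-spline
   interpolate each cell to a common number of points (the subtree
   median);
3. binarize rates against the subtree-wide median (1 = high rate);
4. merge the copies (replicate embryos) of each gene by strict majority,
   with all-copies-missing points kept as missing.

Residual missing values below a configurable cap are then treated as low
expression (state 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from bbtd.lineage_io import LineageTree, RawEmbryoFile, build_tree

logger = logging.getLogger(__name__)

MAX_DELAY = 5  # regulatory lags considered: 0..5 interpolation units


@dataclass
class SubtreeDataset:
    """Binary gene-state matrix over lineage-indexed interpolation points.

    ``states[i, p]`` is the Boolean expression state of gene ``i`` at
    point ``p``; ``missing`` marks unobserved entries.  ``prev[p]`` is
    the lineage-path predecessor of point ``p``: the previous point of
    the same cell, or — at a cell's first point — the terminal point of
    its parent cell (so both daughters share the parent history), or -1
    at the first point of a root cell.  ``delta_t`` is the normalized
    time unit between successive interpolations.
    """

    states: np.ndarray  # (N, T) int8 in {0,1}
    missing: np.ndarray  # (N, T) bool
    gene_names: list[str]
    cell_of_point: np.ndarray  # (T,) str
    prev: np.ndarray  # (T,) int, -1 at root-cell first points
    delta_t: float = 1.0
    subtree_label: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.prev = np.asarray(self.prev, dtype=np.int64)
        self.cell_of_point = np.asarray(self.cell_of_point)
        if self.states.shape != self.missing.shape:
            raise ValueError("states/missing shape mismatch")
        if self.states.shape != (len(self.gene_names), len(self.prev)):
            raise ValueError("inconsistent dataset dimensions")

    @property
    def n_genes(self) -> int:
        return self.states.shape[0]

    @property
    def n_points(self) -> int:
        return self.states.shape[1]

    @property
    def root_points(self) -> np.ndarray:
        """Indices of points opening a root-cell segment."""
        return np.flatnonzero(self.prev < 0)

    def lag_indices(self, max_lag: int = MAX_DELAY) -> np.ndarray:
        """(max_lag+1, T) matrix of m-step lineage predecessors.

        Entry [m, p] is the point index m units before point p along its
        lineage path, or -1 where the history does not reach back that
        far.
        """
        T = self.n_points
        L = np.empty((max_lag + 1, T), dtype=np.int64)
        L[0] = np.arange(T)
        for m in range(1, max_lag + 1):
            prev_row = L[m - 1]
            nxt = np.where(prev_row >= 0, self.prev[prev_row], -1)
            L[m] = nxt
        return L

    def usable_points(self, max_lag: int = MAX_DELAY) -> np.ndarray:
        """Points whose full ``max_lag``-step history resolves.

        These are the likelihood's time indices (k >= 6 counted along
        each lineage path when ``max_lag`` is 5).
        """
        return np.flatnonzero(self.lag_indices(max_lag)[max_lag] >= 0)

    def missing_fraction(self) -> np.ndarray:
        """Per-gene fraction of missing points."""
        return self.missing.mean(axis=1)


@dataclass
class IntegrationConfig:
    """Knobs of the integration pipeline.

    ``n_target`` overrides the per-cell interpolation count (default:
    subtree median); ``max_missing_gene``/``max_missing_cell`` are the
    missingness caps standing in for candidate gene/cell selection;
    ``onset_cells``, when given, restricts integration to externally
    provided expression-onset cells and their descendants.
    """

    n_target: int | None = None
    max_missing_gene: float = 0.05
    max_missing_cell: float = 0.5
    onset_cells: Sequence[str] | None = None
    aliases: Mapping[str, str] | None = None


# ---------------------------------------------------------------------------
# Step primitives
# ---------------------------------------------------------------------------

def normalize_lifetime(n_points: int) -> np.ndarray:
    """Step 1: abscissae of a cell's samples on the unit lifetime.

    Returns ``n_points`` uniformly spaced positions with the first at 0
    and the last at 1.
    """
    if n_points < 2:
        raise ValueError("need at least 2 points to normalize a lifetime")
    return np.linspace(0.0, 1.0, n_points)


def expression_rates(intensity: np.ndarray) -> np.ndarray:
    """Step 2a: first-order differences of the fluorescence series.

    Raw intensity rarely decreases, so its increments — not its level —
    carry the expression signal.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size < 2:
        raise ValueError("need at least 2 intensity samples")
    return np.diff(intensity)


def interpolate_cell(rates: np.ndarray, n_target: int) -> np.ndarray:
    """Step 2b: resample a cell's rate series to ``n_target`` points.

    A not-a-knot cubic spline (the classic FMM interpolant up to end
    conditions; both reproduce cubics exactly) is fit on the normalized
    lifetime and evaluated at ``n_target`` equispaced abscissae on
    [0, 1].  Rates sit at the left endpoints of their intervals, so the
    last sliver of the lifetime is a (mild) spline extrapolation.
    """
    rates = np.asarray(rates, dtype=float)
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    new_x = np.linspace(0.0, 1.0, n_target)
    if rates.size == 1:
        logger.debug("single-rate cell replicated to %d points", n_target)
        return np.full(n_target, rates[0])
    x = normalize_lifetime(rates.size)
    if rates.size < 4:  # not-a-knot needs 4 points; fall back to linear
        return np.interp(new_x, x, rates)
    spline = CubicSpline(x, rates, bc_type="not-a-knot", extrapolate=True)
    return spline(new_x)


def choose_n_target(points_per_cell: Sequence[int]) -> int:
    """Median (lower, for even counts) of per-cell point counts."""
    counts = sorted(int(c) for c in points_per_cell)
    if not counts:
        raise ValueError("no cells")
    return counts[(len(counts) - 1) // 2]


def binarize(rates: np.ndarray) -> np.ndarray:
    """Step 3: threshold rates at their subtree-wide median.

    State 1 iff the rate strictly exceeds the median of the given
    values (NaNs ignored); ties and constant input map to 0 ("low").
    """
    rates = np.asarray(rates, dtype=float)
    thresh = np.nanmedian(rates)
    out = (rates > thresh).astype(np.int8)
    out[np.isnan(rates)] = 0
    return out


def merge_copies(copies: np.ndarray, missing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Step 4: strict-majority merge of one gene's replicate embryos.

    At each point, the merged state is 1 iff more than half of the
    *available* copies are 1; points where every copy is missing stay
    missing.  Order of copies is immaterial.
    """
    copies = np.asarray(copies)
    missing = np.asarray(missing, dtype=bool)
    avail = (~missing).sum(axis=0)
    ones = np.where(missing, 0, copies).sum(axis=0)
    merged = (2 * ones > avail).astype(np.int8)
    all_missing = avail == 0
    merged[all_missing] = 0
    return merged, all_missing


def fill_missing(
    dataset: SubtreeDataset, max_missing: float = 0.05
) -> SubtreeDataset:
    """Replace residual missing values by state 0 (low expression rate).

    Genes whose missing fraction exceeds ``max_missing`` are flagged for
    exclusion rather than imputed.
    """
    frac = dataset.missing_fraction()
    over = np.flatnonzero(frac > max_missing)
    if over.size:
        names = [dataset.gene_names[i] for i in over]
        raise ValueError(
            f"genes exceed the missing-value cap ({max_missing:.0%}): {names}"
        )
    states = dataset.states.copy()
    states[dataset.missing] = 0
    return SubtreeDataset(
        states=states,
        missing=np.zeros_like(dataset.missing),
        gene_names=list(dataset.gene_names),
        cell_of_point=dataset.cell_of_point,
        prev=dataset.prev,
        delta_t=dataset.delta_t,
        subtree_label=dataset.subtree_label,
    )


# ---------------------------------------------------------------------------
# Point layout helpers
# ---------------------------------------------------------------------------

def layout_points(
    cell_names: Sequence[str],
    parents: Mapping[str, str | None],
    n_target: int,
) -> tuple[np.ndarray, np.ndarray, dict[str, slice]]:
    """Assign each cell ``n_target`` consecutive points, in tree order.

    Returns (cell_of_point, prev, segment map).  A cell's first point
    links to its parent's last point; root cells start a segment with
    prev = -1.
    """
    order: list[str] = []
    roots = sorted(n for n in cell_names if parents.get(n) is None)
    children: dict[str, list[str]] = {}
    for n in cell_names:
        p = parents.get(n)
        if p is not None:
            children.setdefault(p, []).append(n)
    stack = list(reversed(roots))
    while stack:
        cur = stack.pop()
        order.append(cur)
        stack.extend(reversed(sorted(children.get(cur, []))))
    if len(order) != len(cell_names):
        raise ValueError("parent map does not cover all cells")
    T = n_target * len(order)
    cell_of_point = np.empty(T, dtype=object)
    prev = np.empty(T, dtype=np.int64)
    seg: dict[str, slice] = {}
    for idx, name in enumerate(order):
        lo = idx * n_target
        seg[name] = slice(lo, lo + n_target)
        cell_of_point[lo : lo + n_target] = name
        prev[lo + 1 : lo + n_target] = np.arange(lo, lo + n_target - 1)
        p = parents.get(name)
        prev[lo] = -1 if p is None else seg[p].stop - 1
    return cell_of_point.astype(str), prev, seg


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _restrict_to_onset(tree: LineageTree, onset: Sequence[str]) -> set[str]:
    keep: set[str] = set()
    onset_set = set(onset)
    for name, cell in tree.cells.items():
        cur: str | None = name
        while cur is not None:
            if cur in onset_set:
                keep.add(name)
                break
            cur = tree.cells[cur].parent
    return keep


def integrate(
    files: Sequence[RawEmbryoFile],
    subtree_label: str,
    config: IntegrationConfig | None = None,
) -> SubtreeDataset:
    """Run the four-step integration over a set of per-embryo files.

    Files sharing a gene name are treated as copies of that gene.  The
    union of cells observed in any file defines the subtree layout; a
    copy missing a cell contributes missing values there.  Cells seen in
    fewer than ``1 - max_missing_cell`` of all copies are dropped.
    """
    cfg = config or IntegrationConfig()
    trees: list[tuple[str, LineageTree]] = []
    for raw in files:
        tree = build_tree(raw, subtree_label, aliases=cfg.aliases)
        if cfg.onset_cells is not None:
            keep = _restrict_to_onset(tree, cfg.onset_cells)
            tree.cells = {n: c for n, c in tree.cells.items() if n in keep}
            for c in tree.cells.values():
                if c.parent is not None and c.parent not in tree.cells:
                    c.parent = None
        trees.append((raw.gene_name, tree))
    if not trees:
        raise ValueError("no input files")

    # union cell layout; drop cells observed too rarely across copies
    n_copies_total = len(trees)
    seen_count: dict[str, int] = {}
    for _, tree in trees:
        for name in tree.cells:
            seen_count[name] = seen_count.get(name, 0) + 1
    min_seen = (1.0 - cfg.max_missing_cell) * n_copies_total
    cell_names = sorted(n for n, c in seen_count.items() if c >= min_seen)
    if not cell_names:
        raise ValueError("no cell observed often enough across copies")
    dropped = sorted(set(seen_count) - set(cell_names))
    if dropped:
        logger.info("dropping %d under-observed cells: %s", len(dropped), dropped)

    # consensus parent map over retained cells (longest prefix among them)
    from bbtd.lineage_io import resolve_parent

    parents = {n: resolve_parent(n, cell_names, cfg.aliases) for n in cell_names}

    # Step 2 target count: median points per cell (rates, i.e. diffs)
    per_cell_counts = [
        len(cell.series) - 1
        for _, tree in trees
        for cell in tree.cells.values()
        if cell.name in parents and len(cell.series) >= 2
    ]
    n_target = cfg.n_target or max(2, choose_n_target(per_cell_counts))
    cell_of_point, prev, seg = layout_points(cell_names, parents, n_target)
    T = len(prev)
    logger.info(
        "integration layout: %d cells x %d interpolations = %d points",
        len(cell_names), n_target, T,
    )

    # Steps 1-3 per copy, Step 4 across copies of each gene
    by_gene: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for gene, tree in trees:
        vals = np.full(T, np.nan)
        for name in cell_names:
            cell = tree.cells.get(name)
            if cell is None or len(cell.series) < 2:
                continue
            rates = expression_rates(cell.series)
            vals[seg[name]] = interpolate_cell(rates, n_target)
        states = binarize(vals)
        miss = np.isnan(vals)
        by_gene.setdefault(gene, []).append((states, miss))

    gene_names = sorted(by_gene)
    N = len(gene_names)
    states = np.zeros((N, T), dtype=np.int8)
    missing = np.zeros((N, T), dtype=bool)
    for gi, gene in enumerate(gene_names):
        copies = np.stack([s for s, _ in by_gene[gene]])
        miss = np.stack([m for _, m in by_gene[gene]])
        states[gi], missing[gi] = merge_copies(copies, miss)

    dataset = SubtreeDataset(
        states=states,
        missing=missing,
        gene_names=gene_names,
        cell_of_point=cell_of_point,
        prev=prev,
        subtree_label=subtree_label,
    )
    over = np.flatnonzero(dataset.missing_fraction() > cfg.max_missing_gene)
    if over.size:
        keep = np.setdiff1d(np.arange(N), over)
        logger.info(
            "excluding %d genes over the missing cap: %s",
            over.size, [gene_names[i] for i in over],
        )
        dataset = SubtreeDataset(
            states=states[keep],
            missing=missing[keep],
            gene_names=[gene_names[i] for i in keep],
            cell_of_point=cell_of_point,
            prev=prev,
            subtree_label=subtree_label,
        )
    return fill_missing(dataset, max_missing=cfg.max_missing_gene)
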