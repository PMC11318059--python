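# Methods

## Problem setting

Time-lapse confocal microscopy of *C. elegans* embryos yields, per
embryo, the fluorescence of one labeled gene in every living cell at
1.5-minute intervals, organized along the invariant cell lineage.
Because each embryo carries a different label and the lifetime of a
given cell varies between embryos, series from different files are not
pairwise comparable, and flat time-series methods discard the
parent–child structure. This package (i) integrates such files into a
pairwise binary dataset per founder-cell subtree (AB, C, D, E, MS) and
(ii) infers a signed gene regulatory network with per-edge discrete
time delays by Bayesian inference in a probabilistic Boolean network.

## Data integration

For each cell the lifetime is mapped affinely onto [0, 1] (step 1).
Because raw intensity is nearly monotone, the expression signal is its
first-order difference ("expression rate", step 2a); rates are placed
at the left endpoints of their sampling intervals and resampled by a
not-a-knot cubic spline to a common per-cell count — the lower median
of per-cell rate counts over the subtree (step 2b). The classic FMM
interpolant differs from not-a-knot only in its end conditions; both
reproduce cubic polynomials exactly, which the tests assert. Rates are
binarized against the median of each copy's values across the subtree,
with ties mapped to 0 so constant input is all-low (step 3). Replicate
embryos ("copies") of a gene are merged pointwise by strict majority
over the *available* copies — computing the majority over all copies
would bias merged states toward 0 wherever one copy lacks a cell — and
points missing in every copy stay missing (step 4). Residual missing
values are treated as low expression provided the per-gene missing
fraction is below a cap (default 5%); genes above the cap are excluded.
Candidate-cell selection is likewise expressed as a missingness cap
(cells observed in under half the copies are dropped) plus an optional
externally supplied expression-onset cell list, since onset calls come
from separate experimental work.

The integrated container stores one binary state per gene per
"interpolation point", each point belonging to exactly one cell, and a
lineage predecessor index per point: within a cell the previous point,
at a cell's first point the parent's terminal point (both daughters
share the mother's history), and none at a root cell's first point.
All lag lookups — in the likelihood, the pre-screening and the
simulator — resolve through this chain.

## Model

States s ∈ {0,1}^N evolve on the lineage. With A = (a_ij) ∈ {−1,0,1}
(zero diagonal; self-regulation is not modeled because binarization
suppresses the subtle feedback signals it would require) and delays
δ_ij ∈ {0,…,5} interpolation units, gene i's input at a point is
H_i = Σ_j a_ij s_j^(t−δ_ij). If H_i = 0 the gene keeps its previous
state with probability σ(α) = 1/(1+e^(−α)); otherwise
P(s_i = s) = exp[β(2s−1)H_i] / (e^(βH_i) + e^(−βH_i)), with β an
inverse-temperature noise parameter. The likelihood multiplies these
terms over all genes and all points whose five-step lag history
resolves along the lineage path (within a root segment this is the
sixth point onward). Delay-0 edges condition on the regulator's state
at the same point, which is well defined given observed data.

Priors: a row of A is empty with probability κ, otherwise its
regulator count x follows a truncated exponential c(λ)e^(−λx) on
{1,…,N−1}, the regulator subset is uniform among the C(N−1, x)
choices and signs are independent fair coins. Delays are uniform on
{0,…,5} for present edges; for absent edges a spike-and-slab prior
(0.999 at 0, 0.0002 on each of 1–5) keeps the parameter dimension
fixed. Hyperpriors are α ∼ Γ(1,10), β ∼ Γ(100,100), λ ∼ Γ(490,70),
κ ∼ Beta(6,24), all Gamma distributions in shape–rate form: this gives
β mean 1 (a temperature-like noise level), λ mean 7 (strong sparsity)
and κ mean 0.2, whereas shape–scale would put β near 10⁴, inconsistent
with its role. Under shape–rate, α has prior mean 0.1 (persistence
barely above ½), which is weak for a persistence parameter but is kept
for consistency of parametrization across the four priors.

## Pre-screening

For every ordered pair (target, regulator) and lag m ∈ {0,…,5}, the
target's states at the usable points are crossed with the regulator's
lagged states in a 2×2 table and tested by a two-sided Fisher exact
test. An edge is eliminated when p ≥ θ at every lag — the weakest
aggregation under which "p above threshold" means "no relationship",
and the one compatible with a zero false-negative rate. p-values are
computed by a vectorized hypergeometric tail sum with the standard
relative tie tolerance; the tests assert exact agreement with
`scipy.stats.fisher_exact` and with full enumeration on small tables.
No multiple-testing correction is applied: the screen controls the
MCMC's search space, not a family-wise error rate. The default
θ = 0.05 was calibrated once on priors-drawn synthetic data at the
five real configurations so that roughly 70% of candidates are
eliminated while no ground-truth edge is ever lost; it is configurable.

## Inference

Each retained (a_ij, δ_ij) pair is Gibbs-updated jointly from its
exact conditional over 18 states ({−1,0,1} × {0..5}); joint enumeration
avoids the absorbing spike a separate-update scheme would create. Only
gene i's likelihood terms enter the conditional, and the input rows H_i
and total log-likelihood are maintained incrementally, so one edge
update costs a 13-row vectorized enumeration over the usable points.
α, β, λ move by Gaussian random walks on the log scale and κ on the
logit scale (default scale 0.2, optional burn-in-only adaptation),
with Jacobian-corrected Metropolis–Hastings acceptance; λ and κ read
the network only through the row counts x_i. Chains start from the
empty network, δ = 0 and prior means — a neutral, documented origin —
with chain seeds spawned from the run seed. After discarding the first
half of each chain, the MAP estimate is the retained sample with the
highest joint log posterior across chains; a per-parameter
marginal-mode summary was considered and rejected because only the
joint argmax uses the posterior the sampler actually targets.

## Simulator

Ground truth (A, Δ, α, β, λ, κ) is drawn from the priors; states are
then generated forward along a balanced binary lineage tree grown
breadth-first to the configured cell count, each cell carrying the
configured number of interpolation points (the real datasets' "Gene /
Cell / Inters" dimensions are built in: AB 27/112/24, C 30/51/20,
D 20/12/28, E 40/26/16, MS 29/80/22). The first five indices of a root
cell, which never enter the likelihood, are i.i.d. Bernoulli(1/2) per
gene. Within a time slice genes are generated sequentially in a
topological order of the delay-0 subgraph, so the realized joint law
equals the model's conditional factorization exactly whenever that
subgraph is acyclic; in the (rare, under the sparse prior) cyclic case
the order falls back to a seeded random permutation and a
not-yet-updated delay-0 regulator is read at its previous index. The
generator emulates the structure of the real data — branching
histories shared by daughters, per-cell segments, Table-scale
dimensions — but not fluorescence physics, measurement noise or
missingness; a separate small fixture generator produces raw
fluorescence files (monotone cumulative sums of binary rate templates
plus Gaussian noise, misaligned per-copy lifetimes) solely to exercise
the integration pipeline. Passing synthetic benchmarks therefore
demonstrates correctness of the method under its own generative
assumptions, not robustness to real-data artifacts.

## Numerical choices and problem sizes

All densities are handled in log space with `logaddexp`; the edge
conditional is normalized after subtracting its maximum. Degenerate
inputs are handled explicitly: constant genes yield p = 1 in every
Fisher test and are screened out with a warning; single-point cells
replicate their value at interpolation; empty denominators in the
evaluation metrics give NaN and are excluded from replicate means
(sparse truths occasionally lack negative edges). The replicated
studies shipped with the package use 50 replicates for pre-screening
rates and 6 replicates × 3 chains × 600 iterations for the full
D-configuration pipeline — the smallest configuration, chosen so the
whole study runs in minutes on a laptop; chains reach their
log-posterior plateau within tens of iterations at that scale, and the
50-replicate, longer-chain version of the larger configurations is a
straightforward parameter change.

## Known limitations

Binarization discards graded expression; self-loops are excluded by
design. Convergence is monitored only through log-posterior traces —
with a largely discrete parameter space, formal diagnostics are of
limited value. The likelihood conditions each root segment on its
first five points rather than modeling them. Real-data reconstruction
requires the original fluorescence tables, which are not bundled; the
reader is schema-configurable because the upstream file dialects vary.
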