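"""Recovery metrics for pre-screening and MAP networks, and the
replicate simulation study.

Pre-screening is scored by the eliminated-edge fraction (PR) and the
fraction of ground-truth edges lost (FNR); the signed MAP network by
TPR/PPR (positive edges), TNR/PNR (negative edges); delays by the
fraction of predicted edges whose delay matches the truth (ACC).  All
counts run over off-diagonal entries; ratios with empty denominators
are reported as NaN and excluded from replicate means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from bbtd.inference import MCMCConfig, map_estimate, run_mcmc
from bbtd.prescreen import DEFAULT_THETA, run_prescreen
from bbtd.simulator import draw_truth, make_subtree_config, simulate_dataset

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["PR", "FNR", "TPR", "PPR", "TNR", "PNR", "ACC"]


def _offdiag(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def prescreen_metrics(tilde_A: np.ndarray, truth_A: np.ndarray) -> tuple[float, float]:
    """Pre-screening rate and false negative rate of the retention mask."""
    tilde_A = np.asarray(tilde_A)
    truth_A = np.asarray(truth_A)
    off = _offdiag(tilde_A.shape[0])
    eliminated = (tilde_A == 0) & off
    pr = eliminated.sum() / off.sum()
    true_edges = (truth_A != 0) & off
    fnr = _ratio(int((eliminated & true_edges).sum()), int(true_edges.sum()))
    return float(pr), fnr


def network_metrics(
    A_hat: np.ndarray, truth_A: np.ndarray
) -> tuple[float, float, float, float]:
    """Signed-edge recovery: (TPR, PPR, TNR, PNR) over off-diagonals."""
    A_hat = np.asarray(A_hat)
    truth_A = np.asarray(truth_A)
    off = _offdiag(A_hat.shape[0])
    hit_pos = int(((A_hat == 1) & (truth_A == 1) & off).sum())
    hit_neg = int(((A_hat == -1) & (truth_A == -1) & off).sum())
    tpr = _ratio(hit_pos, int(((truth_A == 1) & off).sum()))
    ppr = _ratio(hit_pos, int(((A_hat == 1) & off).sum()))
    tnr = _ratio(hit_neg, int(((truth_A == -1) & off).sum()))
    pnr = _ratio(hit_neg, int(((A_hat == -1) & off).sum()))
    return tpr, ppr, tnr, pnr


def delay_accuracy(
    Delta_hat: np.ndarray, A_hat: np.ndarray, truth_Delta: np.ndarray
) -> float:
    """Fraction of predicted edges whose delay equals the truth."""
    A_hat = np.asarray(A_hat)
    off = _offdiag(A_hat.shape[0])
    predicted = (A_hat != 0) & off
    match = predicted & (np.asarray(Delta_hat) == np.asarray(truth_Delta))
    return _ratio(int(match.sum()), int(predicted.sum()))


@dataclass
class EvaluationReport:
    """Per-replicate metric table and NaN-excluding means."""

    subtree_label: str
    per_replicate: pd.DataFrame  # columns METRIC_COLUMNS, one row per replicate

    @property
    def means(self) -> pd.Series:
        return self.per_replicate.mean(skipna=True)

    def to_tsv(self, path: str | Path) -> None:
        self.per_replicate.to_csv(path, sep="\t", index_label="replicate")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtree": self.subtree_label,
            "n_replicates": len(self.per_replicate),
            "means": {k: _none_if_nan(v) for k, v in self.means.items()},
            "per_replicate": [
                {k: _none_if_nan(v) for k, v in row.items()}
                for _, row in self.per_replicate.iterrows()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _none_if_nan(v: float) -> float | None:
    return None if (isinstance(v, float) and np.isnan(v)) else float(v)


def replicate_study(
    subtree_label: str,
    n_replicates: int,
    seed: int = 0,
    mcmc_config: MCMCConfig | None = None,
    theta: float = DEFAULT_THETA,
    run_inference: bool = True,
) -> EvaluationReport:
    """Draw-truth / simulate / prescreen / infer / score, replicated.

    Each replicate draws a fresh ground truth from the priors,
    simulates a dataset at the subtree's real dimensions, pre-screens,
    and (optionally) runs the MCMC to a MAP network.  Replicate seeds
    are spawned from ``seed`` so any single replicate is reproducible
    in isolation.
    """
    config = make_subtree_config(subtree_label)
    rows = []
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth_net, truth_params, truth_hyper = draw_truth(config.n_genes, rng)
        dataset = simulate_dataset((truth_net, truth_params, truth_hyper), config, rng)
        mask = run_prescreen(dataset, theta=theta)
        pr, fnr = prescreen_metrics(mask.tilde_A, truth_net.A)
        row = dict.fromkeys(METRIC_COLUMNS, float("nan"))
        row.update(PR=pr, FNR=fnr)
        if run_inference:
            mcfg = mcmc_config or MCMCConfig()
            mcfg = MCMCConfig(
                n_iterations=mcfg.n_iterations,
                n_chains=mcfg.n_chains,
                proposal_scales=dict(mcfg.proposal_scales),
                adapt_during_burnin=mcfg.adapt_during_burnin,
                seed=int(child.generate_state(1)[0] % 2**31),
            )
            samples = run_mcmc(dataset, mask, mcfg)
            est = map_estimate(samples)
            tpr, ppr, tnr, pnr = network_metrics(est.network.A, truth_net.A)
            acc = delay_accuracy(est.network.Delta, est.network.A, truth_net.Delta)
            row.update(TPR=tpr, PPR=ppr, TNR=tnr, PNR=pnr, ACC=acc)
        rows.append(row)
        logger.info("replicate %d/%d done: %s", rep + 1, n_replicates, row)
    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return EvaluationReport(subtree_label=subtree_label, per_replicate=table)
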