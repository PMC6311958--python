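"""Synthetic binary expression data with known confounding and known
causal miRNA->mRNA edges.

Each sample is generated in three stages: hidden regulators (transcription
factors / pathways) switch on independently with probability ``q``; every
visible feature (miRNA or mRNA) turns on with probability
sigmoid(bias + loadings . h); and mRNAs additionally receive the planted
causal effects of whichever miRNAs are on.  Pairs that share a hidden
regulator but have no planted edge are *confounded*: they co-vary in the
data although neither regulates the other — the structure the causal deep
net is meant to tell apart from genuine regulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import BinaryExpressionMatrix, from_blocks

__all__ = ["SimConfig", "GroundTruth", "simulate", "gold_standard_from_truth"]


@dataclass
class SimConfig:
    """Generator settings.

    Defaults describe the standard desk-scale scenario: 300 tumors,
    30 miRNAs, 120 mRNAs, 6 hidden regulators each on with probability
    0.3, hidden->visible loadings of +3, and 15 planted repressive edges
    of strength -4 on a background bias of -2 (baseline on-rate ~12%,
    regulator-driven on-rate ~73%).
    """

    n_samples: int = 300
    n_mirna: int = 30
    n_mrna: int = 120
    n_hidden_regulators: int = 6
    hidden_on_prob: float = 0.3
    loading_scale: float = 3.0
    n_causal_edges: int = 15
    causal_effect_size: float = -4.0
    background_bias: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hidden_on_prob < 1):
            raise ValueError("hidden_on_prob must lie in (0, 1)")
        if self.n_causal_edges > self.n_mirna * self.n_mrna:
            raise ValueError(
                "n_causal_edges exceeds the number of (miRNA, mRNA) pairs"
            )
        for name in ("n_samples", "n_mirna", "n_mrna",
                     "n_hidden_regulators"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted.

    hidden_loadings : (n_hidden, n_visible) with visibles in canonical
        [mRNA | miRNA] order.
    causal_edges : list of (mirna_id, mrna_id, signed effect).
    confounded_pairs : (mirna_id, mrna_id) sharing >= 1 hidden regulator
        with no planted edge; disjoint from causal_edges by construction.
    hidden_states : the (n_samples, n_hidden) regulator states actually
        drawn, kept for diagnostics (e.g. conditional-independence checks).
    """

    hidden_loadings: np.ndarray
    causal_edges: list[tuple[str, str, float]]
    confounded_pairs: list[tuple[str, str]]
    pi_true: np.ndarray = field(repr=False, default=None)
    hidden_states: np.ndarray = field(repr=False, default=None)


def simulate(config: SimConfig) -> tuple[BinaryExpressionMatrix, GroundTruth]:
    """Draw one dataset; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_mi, n_mr, n_h = config.n_mirna, config.n_mrna, config.n_hidden_regulators
    n_vis = n_mi + n_mr

    mrna_ids = [f"mRNA_{o:04d}" for o in range(n_mr)]
    mirna_ids = [f"miR_{k:04d}" for k in range(n_mi)]

    # sparse positive loadings: each visible driven by 1-2 regulators
    loadings = np.zeros((n_h, n_vis))  # canonical order [mRNA | miRNA]
    for j in range(n_vis):
        k = rng.integers(1, min(2, n_h) + 1)
        regs = rng.choice(n_h, size=k, replace=False)
        loadings[regs, j] = config.loading_scale
    L_mr, L_mi = loadings[:, :n_mr], loadings[:, n_mr:]

    # planted signed causal edges
    pi_true = np.zeros((n_mr, n_mi))
    flat = rng.choice(n_mr * n_mi, size=config.n_causal_edges, replace=False)
    rows, cols = np.unravel_index(flat, (n_mr, n_mi))
    pi_true[rows, cols] = config.causal_effect_size
    causal_edges = [
        (mirna_ids[k], mrna_ids[o], float(pi_true[o, k]))
        for o, k in zip(rows, cols)
    ]

    h = (rng.random((config.n_samples, n_h))
         < config.hidden_on_prob).astype(float)
    p_mi = expit(config.background_bias + h @ L_mi)
    mi = (rng.random(p_mi.shape) < p_mi).astype(np.int8)
    p_mr = expit(config.background_bias + h @ L_mr + mi @ pi_true.T)
    mr = (rng.random(p_mr.shape) < p_mr).astype(np.int8)

    extreme = min(p_mi.min(), p_mr.min(), 1 - p_mi.max(), 1 - p_mr.max())
    if extreme < 1e-12:
        warnings.warn(
            "degenerate configuration: some on-probabilities are "
            "numerically 0 or 1", stacklevel=2,
        )

    shares = (L_mi > 0).T.astype(int) @ (L_mr > 0).astype(int)  # (n_mi, n_mr)
    confounded = [
        (mirna_ids[k], mrna_ids[o])
        for k, o in zip(*np.nonzero(shares))
        if pi_true[o, k] == 0.0
    ]

    matrix = from_blocks(
        mr, mi,
        sample_ids=[f"S{s:04d}" for s in range(config.n_samples)],
        mrna_ids=mrna_ids, mirna_ids=mirna_ids,
    )
    truth = GroundTruth(
        hidden_loadings=loadings,
        causal_edges=causal_edges,
        confounded_pairs=confounded,
        pi_true=pi_true,
        hidden_states=h,
    )
    return matrix, truth


def gold_standard_from_truth(truth: GroundTruth) -> pd.DataFrame:
    """Two-column (mirna_id, mrna_id) list of the planted edges — the
    synthetic stand-in for an experimentally validated pair database."""
    return pd.DataFrame(
        [(m, t) for m, t, _ in truth.causal_edges],
        columns=["mirna_id", "mrna_id"],
    )
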