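"""Standard synthetic benchmarks: parameter recovery and the permutation
control.

These encode the package's reference study conditions — the default
generator scenario (300 samples, 30 miRNA, 120 mRNA, 6 hidden regulators,
15 planted repressive edges) and a fixed training protocol — so that the
same experiment is run identically by the test suite, the acceptance
script and the CLI.

Protocol: bottom semi-RBM and one upper RBM of sizes (64, 32), sparsity
target 0.2 with penalty weight 0.1 on the first hidden layer, CD-1 with
learning rate 0.05, momentum 0.5, batch 50, weight decay 0.01 (which
suppresses the diffuse drift of the directed weights so the planted edges
stand out), 150 epochs per layer, then 30 epochs of full-batch
autoencoder fine-tuning at rate 1e-3.
"""

from __future__ import annotations

import numpy as np

from .evaluate import (
    correlation_baseline,
    extract_interactions,
    pair_auroc,
    score_predictions,
)
from .model import Architecture, MCadet, permute_control
from .semi_rbm import TrainConfig
from .simulate import SimConfig, simulate

__all__ = [
    "scenario_architecture",
    "scenario_train_config",
    "recovery_benchmark",
    "permutation_benchmark",
]


def scenario_architecture() -> Architecture:
    return Architecture(hidden_sizes=(64, 32), sparsity_target=0.2)


def scenario_train_config(seed: int, epochs: int = 150) -> TrainConfig:
    return TrainConfig(
        learning_rate=0.05,
        epochs=epochs,
        batch_size=50,
        momentum=0.5,
        weight_decay=1e-2,
        sparsity_lambda=0.1,
        seed=seed,
    )


def recovery_benchmark(n_seeds: int = 5, base_seed: int = 0) -> dict:
    """Train on the default scenario over several seeds and measure how
    well the learned directed weights recover the planted edges.

    Returns per-seed and mean AUROC of |pi| against the planted edge set,
    plus the PPV of the top-5% prediction set and of the correlation
    baseline truncated to the same number of pairs.
    """
    aurocs, ppv_model, ppv_corr = [], [], []
    for i in range(n_seeds):
        seed = base_seed + i
        data, truth = simulate(SimConfig(seed=seed))
        res = MCadet(data, scenario_architecture()).fit(
            scenario_train_config(seed + 10_000),
            finetune_epochs=30,
            finetune_lr=1e-3,
        )
        planted = truth.pi_true != 0
        aurocs.append(pair_auroc(np.abs(res.pi), planted))
        gold = {(m, t) for m, t, _ in truth.causal_edges}
        pred = extract_interactions(res).kept_pairs()
        ppv_model.append(score_predictions(pred, gold).ppv)
        corr = correlation_baseline(data)
        top = corr.nsmallest(len(pred), "p")
        pred_corr = set(zip(top["mirna_id"], top["mrna_id"]))
        ppv_corr.append(score_predictions(pred_corr, gold).ppv)
    return {
        "auroc": aurocs,
        "auroc_mean": float(np.mean(aurocs)),
        "ppv_model": ppv_model,
        "ppv_model_mean": float(np.mean(ppv_model)),
        "ppv_corr": ppv_corr,
        "ppv_corr_mean": float(np.mean(ppv_corr)),
        "n_pairs": 30 * 120,
        "n_seeds": n_seeds,
    }


def permutation_benchmark(n_seeds: int = 5, base_seed: int = 0,
                          epochs: int = 60) -> dict:
    """Reconstruction error on structured versus column-permuted data.

    The same architecture, config and seeds are used for both fits; the
    permuted data keep every feature's marginal frequency but lose all
    feature-to-feature covariation, so a model that captures real
    structure reconstructs them worse.
    """
    structured, permuted = [], []
    for i in range(n_seeds):
        seed = base_seed + i
        data, _ = simulate(SimConfig(seed=seed))
        perm = permute_control(data, np.random.default_rng(seed + 77_000))
        cfg = scenario_train_config(seed + 20_000, epochs=epochs)
        arch = scenario_architecture()
        structured.append(
            MCadet(data, arch).fit(cfg).reconstruction_error()
        )
        permuted.append(
            MCadet(perm, arch).fit(cfg).reconstruction_error()
        )
    return {
        "structured": structured,
        "structured_mean": float(np.mean(structured)),
        "permuted": permuted,
        "permuted_mean": float(np.mean(permuted)),
        "n_seeds": n_seeds,
    }
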