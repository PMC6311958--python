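import numpy as np
import pytest

from mcadet import Architecture, MCadet, SemiRBMParams, SimConfig, TrainConfig
from mcadet import simulate as run_simulate


@pytest.fixture
def tiny_params() -> SemiRBMParams:
    """3 visible (2 mRNA + 1 miRNA) x 2 hidden, nonzero Pi — small enough
    for exact enumeration."""
    rng = np.random.default_rng(7)
    return SemiRBMParams(
        W=rng.normal(0.0, 0.8, (3, 2)),
        Pi=rng.normal(0.0, 1.0, (2, 1)),
        bias_mrna=rng.normal(0.0, 0.5, 2),
        bias_mirna=rng.normal(0.0, 0.5, 1),
        bias_hidden=rng.normal(0.0, 0.5, 2),
    )


@pytest.fixture
def small_data():
    """A small synthetic dataset with planted structure (120 samples,
    8 miRNA, 30 mRNA)."""
    cfg = SimConfig(
        n_samples=120, n_mirna=8, n_mrna=30, n_hidden_regulators=3,
        n_causal_edges=4, seed=11,
    )
    return run_simulate(cfg)


@pytest.fixture
def small_fit(small_data):
    """A briefly trained small model with causal edges and sparsity."""
    data, truth = small_data
    arch = Architecture(hidden_sizes=(16, 8), sparsity_target=0.2)
    cfg = TrainConfig(epochs=15, batch_size=40, seed=3, sparsity_lambda=0.1)
    return MCadet(data, arch).fit(cfg), data, truth
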