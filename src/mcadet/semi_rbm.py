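"""Semi-restricted Boltzmann machine with directed miRNA->mRNA edges.

The bottom layer of the causal deep net is an RBM over the concatenated
(mRNA, miRNA) visible vector, augmented with a directed weight matrix
``Pi`` (n_mrna x n_mirna) from miRNA visible units to mRNA visible units.

Positive phase: hidden units are driven by all visibles exactly as in a
standard RBM; ``Pi`` plays no role.

Negative phase (asymmetric reconstruction): miRNA visibles are
reconstructed from the hidden layer alone, then mRNA visibles from the
hidden layer *plus* the reconstructed miRNA states through ``Pi``.  This
asymmetry is what lets the model separate correlation explained by shared
hidden regulators (carried by ``W``) from directed regulation (carried by
``Pi``, whose sign encodes activation/repression).

Training is contrastive divergence: parameter moves proportional to the
difference between data and model statistics,

    dW_ij  ~ <v_i h_j>_data - <v_i h_j>_model
    dPi_ok ~ <v_mrna_o v_mirna_k>_data - <v_mrna_o v_mirna_k>_model

with an optional sparsity penalty lambda * sum_j |p - mean_j|^2 on the
mean hidden activations, which biases the first hidden layer toward a
small fraction of active units (a few regulators explain most of the
transcriptome-wide change).

Row convention for ``W``: mRNA block first, then miRNA block.  A model
with ``n_mirna = 0`` (or ``Pi`` identically zero and frozen) reduces
exactly to a standard RBM; the upper layers of the deep net reuse this
machinery in that degenerate form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .data import ShapeError

__all__ = [
    "SemiRBMParams",
    "TrainConfig",
    "GradientStats",
    "init_params",
    "hidden_activation",
    "mirna_reconstruction",
    "mrna_reconstruction",
    "cd_step",
    "sparsity_penalty",
    "apply_update",
    "mean_field_reconstruction",
    "train_semi_rbm",
    "exact_joint_oracle",
    "chain_stationary_oracle",
]


@dataclass
class SemiRBMParams:
    """Bottom-layer parameters.

    W : (n_visible, n_hidden), rows ordered [mRNA block; miRNA block].
    Pi : (n_mrna, n_mirna) directed miRNA->mRNA weights.
    bias_mrna, bias_mirna : visible biases per block.
    bias_hidden : hidden biases.
    """

    W: np.ndarray
    Pi: np.ndarray
    bias_mrna: np.ndarray
    bias_mirna: np.ndarray
    bias_hidden: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W", "Pi", "bias_mrna", "bias_mirna", "bias_hidden"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite entries")
        n_mrna, n_mirna = self.Pi.shape
        if self.bias_mrna.shape != (n_mrna,):
            raise ShapeError(
                f"bias_mrna has length {self.bias_mrna.size}, "
                f"Pi implies n_mrna={n_mrna}"
            )
        if self.bias_mirna.shape != (n_mirna,):
            raise ShapeError(
                f"bias_mirna has length {self.bias_mirna.size}, "
                f"Pi implies n_mirna={n_mirna}"
            )
        if self.W.shape != (n_mrna + n_mirna, self.bias_hidden.size):
            raise ShapeError(
                f"W has shape {self.W.shape}, expected "
                f"({n_mrna + n_mirna}, {self.bias_hidden.size})"
            )

    @property
    def n_mrna(self) -> int:
        return self.Pi.shape[0]

    @property
    def n_mirna(self) -> int:
        return self.Pi.shape[1]

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    @property
    def W_mrna(self) -> np.ndarray:
        return self.W[: self.n_mrna]

    @property
    def W_mirna(self) -> np.ndarray:
        return self.W[self.n_mrna :]

    def copy(self) -> "SemiRBMParams":
        return SemiRBMParams(
            W=self.W.copy(),
            Pi=self.Pi.copy(),
            bias_mrna=self.bias_mrna.copy(),
            bias_mirna=self.bias_mirna.copy(),
            bias_hidden=self.bias_hidden.copy(),
        )


@dataclass
class TrainConfig:
    """Contrastive-divergence hyperparameters.

    ``sparsity_target`` (p) is the desired mean on-fraction of hidden
    units, weighted by ``sparsity_lambda``; a lambda of 0 disables the
    penalty regardless of the target.
    """

    learning_rate: float = 0.05
    epochs: int = 50
    batch_size: int = 100
    cd_steps: int = 1
    momentum: float = 0.5
    weight_decay: float = 0.0
    sparsity_target: float = 0.2
    sparsity_lambda: float = 0.0
    seed: int = 0
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.sparsity_target <= 1):
            raise ValueError("sparsity_target must lie in (0, 1]")
        if self.epochs < 0 or self.batch_size < 1 or self.cd_steps < 1:
            raise ValueError("epochs >= 0, batch_size >= 1, cd_steps >= 1")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must lie in [0, 1)")
        if self.weight_decay < 0 or self.sparsity_lambda < 0:
            raise ValueError("weight_decay and sparsity_lambda must be >= 0")


@dataclass
class GradientStats:
    """CD statistics (data minus model), batch-averaged, unscaled by the
    learning rate.  ``positive_hidden_mean`` is the batch mean of
    P(h_j=1|v) on the data; ``positive_hidden_actderiv`` its exact
    derivative w.r.t. the hidden bias, used to chain the sparsity penalty.
    """

    dW: np.ndarray
    dPi: np.ndarray
    dbias_mrna: np.ndarray
    dbias_mirna: np.ndarray
    dbias_hidden: np.ndarray
    positive_hidden_mean: np.ndarray
    positive_hidden_actderiv: np.ndarray = field(default=None, repr=False)


def init_params(
    n_mrna: int, n_mirna: int, n_hidden: int, config: TrainConfig
) -> SemiRBMParams:
    """Gaussian weights of scale ``init_scale``, zero biases."""
    rng = np.random.default_rng(config.seed)
    return SemiRBMParams(
        W=rng.normal(0.0, config.init_scale, (n_mrna + n_mirna, n_hidden)),
        Pi=rng.normal(0.0, config.init_scale, (n_mrna, n_mirna)),
        bias_mrna=np.zeros(n_mrna),
        bias_mirna=np.zeros(n_mirna),
        bias_hidden=np.zeros(n_hidden),
    )


def _check_visible(v: np.ndarray, params: SemiRBMParams) -> np.ndarray:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != params.n_visible:
        raise ShapeError(
            f"visible batch has {v.shape[1]} columns, model expects "
            f"{params.n_visible} (= {params.n_mrna} mRNA + "
            f"{params.n_mirna} miRNA)"
        )
    return v


def hidden_activation(v: np.ndarray, params: SemiRBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigmoid(b_j + sum_i W_ij v_i).

    Both blocks drive the hidden units; ``Pi`` plays no role here.
    """
    v = _check_visible(v, params)
    return expit(params.bias_hidden + v @ params.W)


def mirna_reconstruction(h: np.ndarray, params: SemiRBMParams) -> np.ndarray:
    """P(v_mirna_k = 1 | h): hidden layer only, independent of mRNA and Pi."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != params.n_hidden:
        raise ShapeError(
            f"hidden batch has {h.shape[1]} columns, model has "
            f"{params.n_hidden} hidden units"
        )
    return expit(params.bias_mirna + h @ params.W_mirna.T)


def mrna_reconstruction(
    h: np.ndarray, v_mirna: np.ndarray, params: SemiRBMParams
) -> np.ndarray:
    """P(v_mrna_o = 1 | h, v_mirna): hidden layer plus miRNA through Pi."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    v_mirna = np.atleast_2d(np.asarray(v_mirna, dtype=float))
    if h.shape[1] != params.n_hidden:
        raise ShapeError(
            f"hidden batch has {h.shape[1]} columns, model has "
            f"{params.n_hidden} hidden units"
        )
    if v_mirna.shape[1] != params.n_mirna:
        raise ShapeError(
            f"miRNA batch has {v_mirna.shape[1]} columns, model has "
            f"{params.n_mirna} miRNA units"
        )
    return expit(
        params.bias_mrna + h @ params.W_mrna.T + v_mirna @ params.Pi.T
    )


def cd_step(
    v: np.ndarray,
    params: SemiRBMParams,
    config: TrainConfig,
    rng: np.random.Generator,
    require_binary: bool = True,
    update_pi: bool = True,
) -> GradientStats:
    """One contrastive-divergence estimate on a batch.

    ``v`` has columns in canonical order [mRNA | miRNA].  The negative
    chain samples h from the data, then for each of ``cd_steps`` rounds
    draws binary miRNA states from h alone, binary mRNA states from h and
    the sampled miRNA states, and finally re-activates the hidden layer.
    Negative visible statistics use the sampled binary states; negative
    hidden statistics use the final activation probabilities.

    With ``update_pi=False`` the chain still honours Pi but dPi is zeroed,
    which (for Pi == 0) makes the whole step identical to vanilla CD-k.
    """
    v = _check_visible(v, params)
    s = v.shape[0]
    if s == 0:
        raise ValueError("cd_step requires a non-empty batch")
    if require_binary and not np.isin(v, (0.0, 1.0)).all():
        raise ValueError("cd_step expects binary visible data")
    n_mrna = params.n_mrna
    v_mrna, v_mirna = v[:, :n_mrna], v[:, n_mrna:]

    # positive phase
    ph = hidden_activation(v, params)
    pos_W = v.T @ ph
    pos_Pi = v_mrna.T @ v_mirna

    # negative phase: asymmetric reconstruction chain
    h_s = (rng.random((s, params.n_hidden)) < ph).astype(float)
    for step in range(config.cd_steps):
        u_v = rng.random((s, params.n_visible))
        p_mi = mirna_reconstruction(h_s, params)
        v_mi = (u_v[:, n_mrna:] < p_mi).astype(float)
        p_mr = mrna_reconstruction(h_s, v_mi, params)
        v_mr = (u_v[:, :n_mrna] < p_mr).astype(float)
        v_neg = np.hstack([v_mr, v_mi])
        ph_neg = hidden_activation(v_neg, params)
        if step < config.cd_steps - 1:
            h_s = (rng.random((s, params.n_hidden)) < ph_neg).astype(float)

    neg_W = v_neg.T @ ph_neg
    neg_Pi = v_mr.T @ v_mi

    dPi = (pos_Pi - neg_Pi) / s if update_pi else np.zeros_like(params.Pi)
    return GradientStats(
        dW=(pos_W - neg_W) / s,
        dPi=dPi,
        dbias_mrna=(v_mrna - v_mr).mean(axis=0),
        dbias_mirna=(v_mirna - v_mi).mean(axis=0),
        dbias_hidden=(ph - ph_neg).mean(axis=0),
        positive_hidden_mean=ph.mean(axis=0),
        positive_hidden_actderiv=(ph * (1.0 - ph)).mean(axis=0),
    )


def sparsity_penalty(
    positive_hidden_mean: np.ndarray, p: float, lam: float
) -> tuple[float, np.ndarray]:
    """Penalty lambda * sum_j |p - mean_j|^2 and its gradient w.r.t. the
    mean activations (2*lambda*(mean - p)), to be chained into the hidden
    bias update."""
    if not (0 < p <= 1):
        raise ValueError("sparsity target p must lie in (0, 1]")
    m = np.asarray(positive_hidden_mean, dtype=float)
    if ((m < 0) | (m > 1)).any():
        raise ValueError("mean activations must lie in [0, 1]")
    penalty = lam * float(np.sum((p - m) ** 2))
    grad = 2.0 * lam * (m - p)
    return penalty, grad


def apply_update(
    params: SemiRBMParams,
    grads: GradientStats,
    config: TrainConfig,
    velocity: dict[str, np.ndarray],
    sparsity_target: float | None = None,
    update_pi: bool = True,
) -> None:
    """In-place momentum ascent on the CD statistics, with optional weight
    decay and the sparsity penalty chained into the hidden biases."""
    db_hidden = grads.dbias_hidden
    if sparsity_target is not None and config.sparsity_lambda > 0:
        _, grad_mean = sparsity_penalty(
            grads.positive_hidden_mean, sparsity_target, config.sparsity_lambda
        )
        # descend the penalty: d mean_j / d b_j = mean of p(1-p) over batch
        db_hidden = db_hidden - grad_mean * grads.positive_hidden_actderiv
    moves = {
        "W": grads.dW - config.weight_decay * params.W,
        "Pi": (grads.dPi - config.weight_decay * params.Pi)
        if update_pi
        else np.zeros_like(params.Pi),
        "bias_mrna": grads.dbias_mrna,
        "bias_mirna": grads.dbias_mirna,
        "bias_hidden": db_hidden,
    }
    for name, move in moves.items():
        vel = velocity.setdefault(name, np.zeros_like(getattr(params, name)))
        vel *= config.momentum
        vel += config.learning_rate * move
        getattr(params, name)[...] += vel


def mean_field_reconstruction(
    v: np.ndarray, params: SemiRBMParams
) -> np.ndarray:
    """Deterministic one-pass reconstruction probabilities, canonical order.

    Hidden probabilities from the data, then miRNA probabilities from the
    hidden probabilities, then mRNA probabilities using the miRNA
    probabilities through Pi (mean field, no sampling)."""
    ph = hidden_activation(v, params)
    p_mi = mirna_reconstruction(ph, params)
    p_mr = mrna_reconstruction(ph, p_mi, params)
    return np.hstack([p_mr, p_mi])


def train_semi_rbm(
    v: np.ndarray,
    n_hidden: int,
    config: TrainConfig,
    n_mirna: int,
    sparsity_target: float | None = None,
    update_pi: bool = True,
    require_binary: bool = True,
    params: SemiRBMParams | None = None,
) -> tuple[SemiRBMParams, list[tuple[int, float]]]:
    """Mini-batch CD training of one (semi-)RBM layer.

    ``v`` is the training batch in canonical [mRNA | miRNA] order; with
    ``n_mirna=0`` this trains a standard RBM (the upper layers).  Returns
    the parameters and a per-epoch log of the mean squared mean-field
    reconstruction error per sample.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n_mrna = v.shape[1] - n_mirna
    if params is None:
        params = init_params(n_mrna, n_mirna, n_hidden, config)
    else:
        params = params.copy()
    rng = np.random.default_rng(config.seed + 1)
    velocity: dict[str, np.ndarray] = {}
    log: list[tuple[int, float]] = []
    n = v.shape[0]
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = v[order[start : start + config.batch_size]]
            grads = cd_step(
                batch, params, config, rng,
                require_binary=require_binary, update_pi=update_pi,
            )
            apply_update(
                params, grads, config, velocity,
                sparsity_target=sparsity_target, update_pi=update_pi,
            )
        recon = mean_field_reconstruction(v, params)
        err = float(np.sum((v - recon) ** 2) / n)
        log.append((epoch, err))
    return params, log


# ---------------------------------------------------------------------
# enumeration oracles (tiny models only; used for testing the machinery)
# ---------------------------------------------------------------------

def _enumerate_states(n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((1, 0))
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


@dataclass
class JointTable:
    """Exact Boltzmann distribution over all (v, h) states of a tiny model,
    for the energy E(v,h) = -a.v - b.h - v'Wh - v_mrna' Pi v_mirna."""

    params: SemiRBMParams
    v_states: np.ndarray  # (2^nv, nv) canonical order [mRNA | miRNA]
    h_states: np.ndarray  # (2^nh, nh)
    p: np.ndarray  # (2^nv, 2^nh), sums to 1

    def marginal_v(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def hidden_conditional(self, v: np.ndarray) -> np.ndarray:
        """P(h_j = 1 | v) for one visible configuration, from the table."""
        v = np.asarray(v, dtype=float).ravel()
        idx = np.flatnonzero((self.v_states == v).all(axis=1))
        if idx.size != 1:
            raise ValueError("visible configuration not in the state table")
        row = self.p[idx[0]]
        return (row[:, None] * self.h_states).sum(axis=0) / row.sum()

    def expect_vh(self) -> np.ndarray:
        """E[v_i h_j] under the joint."""
        return np.einsum(
            "vh,vi,hj->ij", self.p, self.v_states, self.h_states
        )

    def expect_mrna_mirna(self) -> np.ndarray:
        """E[v_mrna_o v_mirna_k] under the joint."""
        n_mrna = self.params.n_mrna
        pv = self.marginal_v()
        return np.einsum(
            "v,vo,vk->ok", pv, self.v_states[:, :n_mrna],
            self.v_states[:, n_mrna:],
        )


def exact_joint_oracle(params: SemiRBMParams) -> JointTable:
    """Brute-force Boltzmann table for models with <= 12 total units."""
    n_v, n_h = params.n_visible, params.n_hidden
    if 2 ** (n_v + n_h) > 4096:
        raise ValueError(
            f"model too large for enumeration: 2^({n_v}+{n_h}) states"
        )
    v_states = _enumerate_states(n_v)
    h_states = _enumerate_states(n_h)
    n_mrna = params.n_mrna
    a = np.concatenate([params.bias_mrna, params.bias_mirna])
    # -E(v,h) for every pair of states
    lin_v = v_states @ a + np.einsum(
        "vo,ok,vk->v", v_states[:, :n_mrna], params.Pi, v_states[:, n_mrna:]
    )
    lin_h = h_states @ params.bias_hidden
    inter = v_states @ params.W @ h_states.T
    logp = lin_v[:, None] + lin_h[None, :] + inter
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return JointTable(params=params, v_states=v_states, h_states=h_states, p=p)


@dataclass
class ChainStationary:
    """Exact stationary law of the asymmetric reconstruction chain.

    The chain v -> h ~ P(h|v) -> v' (miRNA from h, mRNA from h and the new
    miRNA) is not the Gibbs kernel of the Boltzmann joint when Pi != 0, so
    its long-run visible distribution is computed directly from the
    transition matrix; with Pi == 0 it coincides with the Boltzmann
    marginal."""

    params: SemiRBMParams
    v_states: np.ndarray
    pi_v: np.ndarray  # stationary visible marginal

    def expect_vh(self) -> np.ndarray:
        """E[v_i P(h_j=1|v)] — the limit of the chain's negative W stats."""
        ph = hidden_activation(self.v_states, self.params)
        return (self.v_states * self.pi_v[:, None]).T @ ph

    def expect_mrna_mirna(self) -> np.ndarray:
        n_mrna = self.params.n_mrna
        return np.einsum(
            "v,vo,vk->ok", self.pi_v, self.v_states[:, :n_mrna],
            self.v_states[:, n_mrna:],
        )

    def expect_v(self) -> np.ndarray:
        return self.pi_v @ self.v_states


def chain_stationary_oracle(params: SemiRBMParams) -> ChainStationary:
    """Stationary visible distribution of the reconstruction chain, by
    building the full 2^nv x 2^nv transition matrix."""
    n_v, n_h = params.n_visible, params.n_hidden
    if 2 ** (n_v + n_h) > 4096:
        raise ValueError(
            f"model too large for enumeration: 2^({n_v}+{n_h}) states"
        )
    v_states = _enumerate_states(n_v)
    h_states = _enumerate_states(n_h)
    n_mrna = params.n_mrna

    # P(h|v): factorised Bernoulli
    ph = hidden_activation(v_states, params)  # (V, nh)
    p_h_given_v = np.prod(
        np.where(h_states[None, :, :] == 1.0, ph[:, None, :],
                 1.0 - ph[:, None, :]),
        axis=2,
    )  # (V, H)

    # K(v'|h): miRNA from h, mRNA from h and the new miRNA
    p_mi = mirna_reconstruction(h_states, params)  # (H, n_mirna)
    mi_states = v_states[:, n_mrna:]
    mr_states = v_states[:, :n_mrna]
    p_mi_v = np.prod(
        np.where(mi_states[None, :, :] == 1.0, p_mi[:, None, :],
                 1.0 - p_mi[:, None, :]),
        axis=2,
    )  # (H, V)
    k_vh = np.empty((len(h_states), len(v_states)))
    for hi in range(len(h_states)):
        p_mr = mrna_reconstruction(
            np.repeat(h_states[hi : hi + 1], len(v_states), axis=0),
            mi_states, params,
        )
        p_mr_v = np.prod(
            np.where(mr_states == 1.0, p_mr, 1.0 - p_mr), axis=1
        )
        k_vh[hi] = p_mi_v[hi] * p_mr_v

    T = p_h_given_v @ k_vh  # (V, V), rows sum to 1
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi_v = np.real(vecs[:, i])
    pi_v = np.abs(pi_v)
    pi_v /= pi_v.sum()
    return ChainStationary(params=params, v_states=v_states, pi_v=pi_v)
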