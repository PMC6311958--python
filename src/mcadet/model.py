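"""The causal deep belief network: model object, greedy pre-training,
autoencoder fine-tuning, reconstruction, and model selection.

``MCadet`` follows the fit/results idiom: the model object is built from a
:class:`~mcadet.data.BinaryExpressionMatrix` and an :class:`Architecture`,
``fit()`` runs greedy layer-wise pre-training (semi-RBM at the bottom,
standard RBMs above) followed by optional autoencoder fine-tuning, and
returns an :class:`MCadetResults` carrying the parameters, the training
log and the downstream analyses (reconstruction, interaction extraction,
mechanism classification).

The unrolled autoencoder respects the bottom-layer asymmetry: on the way
down, miRNA outputs are produced from the first hidden layer alone and
mRNA outputs from the first hidden layer plus the miRNA reconstruction
through the directed weights Pi.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import BinaryExpressionMatrix, ShapeError, from_blocks
from .semi_rbm import (
    SemiRBMParams,
    TrainConfig,
    hidden_activation,
    train_semi_rbm,
)

__all__ = [
    "Architecture",
    "MCadet",
    "MCadetResults",
    "reconstruction_error",
    "permute_control",
    "select_model",
    "save_model",
    "load_model",
]

_EPS = 1e-12


@dataclass
class Architecture:
    """Network shape and configuration switches.

    The full-scale default mirrors the four-layer 1500/1000/500/250 stack;
    desk-scale analyses use much smaller stacks (e.g. [64, 32]).
    ``sparsity_target`` of None disables the hidden-sparsity penalty;
    ``sparsity_layers`` controls how many hidden layers receive it
    (default 1, i.e. first hidden layer only).
    """

    hidden_sizes: tuple[int, ...] = (1500, 1000, 500, 250)
    use_causal_edges: bool = True
    sparsity_target: float | None = None
    sparsity_layers: int = 1

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) < 1 or any(
            h < 1 for h in self.hidden_sizes
        ):
            raise ValueError("hidden_sizes must be >= 1 positive integers")


@dataclass
class _Autoencoder:
    """Unrolled parameter blocks refined during fine-tuning."""

    enc_W: list[np.ndarray]  # layer l: (m_{l-1}, m_l), m_0 = n_visible
    enc_b: list[np.ndarray]
    dec_R: list[np.ndarray]  # same shapes as enc_W (untied copies)
    dec_c: list[np.ndarray]  # biases of layers 0..L-1 on the way down;
    # dec_c[0] unused (bottom uses the visible biases below)
    bias_mrna: np.ndarray
    bias_mirna: np.ndarray
    Pi: np.ndarray

    def copy(self) -> "_Autoencoder":
        return _Autoencoder(
            enc_W=[w.copy() for w in self.enc_W],
            enc_b=[b.copy() for b in self.enc_b],
            dec_R=[r.copy() for r in self.dec_R],
            dec_c=[c.copy() for c in self.dec_c],
            bias_mrna=self.bias_mrna.copy(),
            bias_mirna=self.bias_mirna.copy(),
            Pi=self.Pi.copy(),
        )


class MCadet:
    """Causal deep net over a binary miRNA/mRNA expression matrix.

    Parameters
    ----------
    data : BinaryExpressionMatrix
        Training matrix; the miRNA/mRNA partition defines the bottom-layer
        blocks (internally ordered mRNA first, then miRNA).
    architecture : Architecture
        Hidden-layer sizes and switches.
    """

    def __init__(self, data: BinaryExpressionMatrix,
                 architecture: Architecture | None = None):
        self.data = data
        self.architecture = architecture or Architecture()
        if data.n_mirna == 0 or data.n_mrna == 0:
            raise ValueError(
                "data must contain both miRNA and mRNA features "
                f"(got {data.n_mirna} miRNA, {data.n_mrna} mRNA)"
            )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, feature_types: pd.Series,
                       architecture: Architecture | None = None) -> "MCadet":
        """Build from a features x samples DataFrame plus a type Series
        mapping each feature ID to 'miRNA' or 'mRNA'."""
        types = feature_types.reindex(frame.index).astype(str).to_numpy()
        matrix = BinaryExpressionMatrix(
            values=frame.to_numpy().T,
            sample_ids=list(frame.columns.astype(str)),
            feature_ids=list(frame.index.astype(str)),
            mirna_index=np.flatnonzero(types == "miRNA"),
            mrna_index=np.flatnonzero(types == "mRNA"),
        )
        return cls(matrix, architecture)

    def fit(self, config: TrainConfig | None = None,
            finetune_epochs: int = 0,
            finetune_lr: float = 0.05) -> "MCadetResults":
        """Greedy pre-training, then optional autoencoder fine-tuning."""
        config = config or TrainConfig()
        results = self._pretrain(config)
        if finetune_epochs > 0:
            results = results.finetune(finetune_epochs, finetune_lr)
        return results

    def _pretrain(self, config: TrainConfig) -> "MCadetResults":
        arch = self.architecture
        data = self.data
        v = data.canonical_values()
        layers: list[SemiRBMParams] = []
        training_log: list[tuple[int, int, float]] = []
        x = v
        n_mirna = data.n_mirna
        for li, n_hidden in enumerate(arch.hidden_sizes):
            bottom = li == 0
            layer_cfg = TrainConfig(
                **{**asdict(config), "seed": config.seed + li}
            )
            sparsity = (
                arch.sparsity_target if li < arch.sparsity_layers else None
            )
            params, log = train_semi_rbm(
                x,
                n_hidden,
                layer_cfg,
                n_mirna=n_mirna if bottom else 0,
                sparsity_target=sparsity,
                update_pi=bottom and arch.use_causal_edges,
                require_binary=bottom,
            )
            if bottom and not arch.use_causal_edges:
                params.Pi[...] = 0.0
            layers.append(params)
            training_log.extend((li, epoch, err) for epoch, err in log)
            # upper layers consume the mean activations of the layer below
            x = hidden_activation(x, params)
        return MCadetResults(
            model=self,
            bottom=layers[0],
            upper_layers=layers[1:],
            config=config,
            training_log=training_log,
        )


@dataclass
class MCadetResults:
    """Fitted causal deep net.

    Attributes
    ----------
    bottom : SemiRBMParams
        Bottom-layer (semi-RBM) parameters; ``bottom.Pi`` holds the
        directed miRNA->mRNA weights used for interaction extraction.
    upper_layers : list of SemiRBMParams with an empty miRNA block
        The standard RBM stack above the bottom layer.
    training_log : list of (layer, epoch, reconstruction_error)
    finetune_log : list of (epoch, cross_entropy) from fine-tuning
    """

    model: MCadet
    bottom: SemiRBMParams
    upper_layers: list[SemiRBMParams]
    config: TrainConfig
    training_log: list[tuple[int, int, float]]
    autoencoder: _Autoencoder | None = None
    finetune_log: list[tuple[int, float]] = field(default_factory=list)

    # -- parameter access --------------------------------------------
    @property
    def architecture(self) -> Architecture:
        return self.model.architecture

    @property
    def pi(self) -> np.ndarray:
        """Directed miRNA->mRNA weights (fine-tuned if available)."""
        if self.autoencoder is not None:
            return self.autoencoder.Pi
        return self.bottom.Pi

    @property
    def pi_pretrained(self) -> np.ndarray:
        return self.bottom.Pi

    def _unroll(self) -> _Autoencoder:
        layers = [self.bottom, *self.upper_layers]
        enc_W = [p.W.copy() for p in layers]
        enc_b = [p.bias_hidden.copy() for p in layers]
        dec_R = [p.W.copy() for p in layers]
        # visible biases of layer l's RBM are the biases of layer l-1 units
        dec_c = [
            np.concatenate([p.bias_mrna, p.bias_mirna]) for p in layers
        ]
        return _Autoencoder(
            enc_W=enc_W,
            enc_b=enc_b,
            dec_R=dec_R,
            dec_c=dec_c,
            bias_mrna=self.bottom.bias_mrna.copy(),
            bias_mirna=self.bottom.bias_mirna.copy(),
            Pi=self.bottom.Pi.copy(),
        )

    # -- reconstruction ----------------------------------------------
    def _forward(self, v: np.ndarray, ae: _Autoencoder):
        """Mean-field up-pass and asymmetric down-pass; returns the
        reconstruction and the intermediate activations for backprop."""
        xs = [v]
        for W, b in zip(ae.enc_W, ae.enc_b):
            xs.append(expit(b + xs[-1] @ W))
        ys = [None] * len(ae.enc_W)
        ys[-1] = xs[-1]
        for l in range(len(ae.enc_W) - 1, 0, -1):
            ys[l - 1] = expit(ae.dec_c[l] + ys[l] @ ae.dec_R[l].T)
        n_mrna = self.bottom.n_mrna
        R1_mr, R1_mi = ae.dec_R[0][:n_mrna], ae.dec_R[0][n_mrna:]
        mi_hat = expit(ae.bias_mirna + ys[0] @ R1_mi.T)
        mr_hat = expit(
            ae.bias_mrna + ys[0] @ R1_mr.T + mi_hat @ ae.Pi.T
        )
        return mr_hat, mi_hat, xs, ys

    def reconstruct(self, data: BinaryExpressionMatrix | None = None
                    ) -> np.ndarray:
        """Deterministic mean-field reconstruction probabilities, returned
        in the column order of the input matrix."""
        data = data or self.model.data
        if data.values.shape[1] != self.bottom.n_visible:
            raise ShapeError(
                f"data has {data.values.shape[1]} features, model expects "
                f"{self.bottom.n_visible}"
            )
        ae = self.autoencoder or self._unroll()
        v = data.canonical_values()
        mr_hat, mi_hat, _, _ = self._forward(v, ae)
        out = np.empty_like(v)
        out[:, : self.bottom.n_mrna] = mr_hat
        out[:, self.bottom.n_mrna :] = mi_hat
        # undo the canonical reordering
        order = np.concatenate([data.mrna_index, data.mirna_index])
        recon = np.empty_like(out)
        recon[:, order] = out
        return recon

    def reconstruction_error(self, data: BinaryExpressionMatrix | None = None,
                             feature_subset=None, mode: str = "squared",
                             reduction: str = "per_sample") -> float:
        data = data or self.model.data
        return reconstruction_error(
            data, self.reconstruct(data), feature_subset=feature_subset,
            mode=mode, reduction=reduction,
        )

    # -- fine-tuning --------------------------------------------------
    def finetune(self, epochs: int, learning_rate: float = 0.05,
                 update_pi: bool = True) -> "MCadetResults":
        """Refine the unrolled autoencoder by full-batch gradient descent
        on the summed reconstruction cross-entropy.  Returns a new results
        object; zero epochs returns an unrolled copy with parameters
        unchanged."""
        ae = (self.autoencoder or self._unroll()).copy()
        v = self.model.data.canonical_values()
        freeze_pi = not (update_pi and self.architecture.use_causal_edges)
        log = list(self.finetune_log)
        start = log[-1][0] if log else 0
        for epoch in range(1, epochs + 1):
            loss, grads = _ae_loss_and_grads(self, v, ae)
            for arr, g in grads:
                if freeze_pi and arr is ae.Pi:
                    continue
                arr -= learning_rate * g
            log.append((start + epoch, loss))
        return MCadetResults(
            model=self.model,
            bottom=self.bottom,
            upper_layers=self.upper_layers,
            config=self.config,
            training_log=self.training_log,
            autoencoder=ae,
            finetune_log=log,
        )

    def finetune_loss(self) -> float:
        """Current reconstruction cross-entropy of the autoencoder."""
        ae = self.autoencoder or self._unroll()
        v = self.model.data.canonical_values()
        loss, _ = _ae_loss_and_grads(self, v, ae)
        return loss

    # -- presentation -------------------------------------------------
    def training_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.training_log, columns=["layer", "epoch", "recon_error"]
        )

    def summary(self) -> str:
        arch = self.architecture
        lines = [
            "Causal deep net (mCADET) results",
            "=" * 40,
            f"samples:            {self.model.data.n_samples}",
            f"features:           {self.bottom.n_mrna} mRNA + "
            f"{self.bottom.n_mirna} miRNA",
            f"hidden layers:      {list(arch.hidden_sizes)}",
            f"causal edges:       "
            f"{'enabled' if arch.use_causal_edges else 'disabled'}",
            f"sparsity target:    {arch.sparsity_target}",
            f"epochs per layer:   {self.config.epochs}",
            f"fine-tune epochs:   {len(self.finetune_log)}",
        ]
        if self.training_log:
            bottom_errs = [e for (l, _, e) in self.training_log if l == 0]
            if bottom_errs:
                lines.append(
                    f"bottom recon err:   {bottom_errs[0]:.4f} -> "
                    f"{bottom_errs[-1]:.4f} (per sample, squared)"
                )
        pi = self.pi
        if arch.use_causal_edges and pi.size:
            flat = np.abs(pi).ravel()
            lines += [
                f"|pi| mean / max:    {flat.mean():.4f} / {flat.max():.4f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self, path)


# ---------------------------------------------------------------------
# autoencoder loss/gradient (shared by finetune and its gradient checks)
# ---------------------------------------------------------------------

def _ae_loss_and_grads(results: MCadetResults, v: np.ndarray,
                       ae: _Autoencoder):
    """Summed reconstruction cross-entropy and gradients for every block.

    Gradients are returned as (parameter_array, gradient) pairs so the
    caller can update in place; order is irrelevant.
    """
    n_mrna = results.bottom.n_mrna
    v_mr, v_mi = v[:, :n_mrna], v[:, n_mrna:]
    mr_hat, mi_hat, xs, ys = results._forward(v, ae)

    mr_c = np.clip(mr_hat, _EPS, 1 - _EPS)
    mi_c = np.clip(mi_hat, _EPS, 1 - _EPS)
    loss = -float(
        np.sum(v_mr * np.log(mr_c) + (1 - v_mr) * np.log(1 - mr_c))
        + np.sum(v_mi * np.log(mi_c) + (1 - v_mi) * np.log(1 - mi_c))
    )

    R1_mr, R1_mi = ae.dec_R[0][:n_mrna], ae.dec_R[0][n_mrna:]
    g_mr = mr_hat - v_mr  # dL/d(pre-sigmoid of mRNA output)
    # miRNA output feeds both its own cross-entropy and the mRNA logits
    g_mi = (mi_hat - v_mi) + (g_mr @ ae.Pi) * mi_hat * (1 - mi_hat)

    grads: list[tuple[np.ndarray, np.ndarray]] = []
    grads.append((ae.Pi, g_mr.T @ mi_hat))
    grads.append((ae.bias_mrna, g_mr.sum(axis=0)))
    grads.append((ae.bias_mirna, g_mi.sum(axis=0)))
    dR1 = np.vstack([g_mr.T @ ys[0], g_mi.T @ ys[0]])
    grads.append((ae.dec_R[0], dR1))

    g_y = g_mr @ R1_mr + g_mi @ R1_mi  # grad w.r.t. ys[0]
    L = len(ae.enc_W)
    for l in range(1, L):
        y_prev, y_cur = ys[l - 1], ys[l]
        g_s = g_y * y_prev * (1 - y_prev)
        grads.append((ae.dec_c[l], g_s.sum(axis=0)))
        grads.append((ae.dec_R[l], g_s.T @ y_cur))
        g_y = g_s @ ae.dec_R[l]
    # top of the decoder is the encoder output
    g_x = g_y
    for l in range(L - 1, -1, -1):
        x_cur = xs[l + 1]
        g_s = g_x * x_cur * (1 - x_cur)
        grads.append((ae.enc_b[l], g_s.sum(axis=0)))
        grads.append((ae.enc_W[l], xs[l].T @ g_s))
        g_x = g_s @ ae.enc_W[l].T
    return loss, grads


# ---------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------

def reconstruction_error(data: BinaryExpressionMatrix, recon: np.ndarray,
                         feature_subset=None, mode: str = "squared",
                         reduction: str = "per_sample") -> float:
    """Discrepancy between the data and a reconstruction.

    mode 'squared' sums (v - p)^2; 'cross_entropy' sums the binary
    log loss.  ``feature_subset`` restricts to the given column indices
    (e.g. the validated targets of one miRNA).  reduction 'sum' reports
    the total, 'per_sample' divides by the number of samples.
    """
    v = np.asarray(data.values, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if recon.shape != v.shape:
        raise ShapeError(
            f"reconstruction shape {recon.shape} != data shape {v.shape}"
        )
    if feature_subset is not None:
        idx = np.asarray(feature_subset, dtype=int)
        if idx.size == 0:
            raise ValueError("feature_subset must not be empty")
        v, recon = v[:, idx], recon[:, idx]
    if mode == "squared":
        err = float(np.sum((v - recon) ** 2))
    elif mode == "cross_entropy":
        p = np.clip(recon, _EPS, 1 - _EPS)
        err = -float(np.sum(v * np.log(p) + (1 - v) * np.log(1 - p)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if reduction == "per_sample":
        err /= v.shape[0]
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return err


def permute_control(data: BinaryExpressionMatrix,
                    rng: np.random.Generator) -> BinaryExpressionMatrix:
    """Independently permute each feature column across samples.

    Marginal on-frequencies are preserved exactly while all feature-to-
    feature statistical structure is destroyed — the negative control used
    to show the network captures real covariation, not marginals."""
    values = data.values.copy()
    for j in range(values.shape[1]):
        values[:, j] = values[rng.permutation(values.shape[0]), j]
    return BinaryExpressionMatrix(
        values=values,
        sample_ids=list(data.sample_ids),
        feature_ids=list(data.feature_ids),
        mirna_index=data.mirna_index.copy(),
        mrna_index=data.mrna_index.copy(),
    )


def select_model(candidates, data: BinaryExpressionMatrix,
                 split_seed: int | None = None,
                 test_fraction: float = 0.2):
    """Train every candidate on a common 80/20 sample split and pick the
    lowest held-out reconstruction error.

    A candidate is ``(Architecture, TrainConfig)`` or
    ``(Architecture, TrainConfig, "permute")``; the latter trains on a
    column-permuted copy of the training split (the negative control) but
    is still scored on the real held-out samples.  Returns
    ``(best_index, report)`` where the report is a DataFrame with one row
    per candidate (train and held-out error)."""
    candidates = [
        (c[0], c[1], len(c) > 2 and bool(c[2])) for c in candidates
    ]
    if not candidates:
        raise ValueError("select_model requires at least one candidate")
    if split_seed is None:
        split_seed = candidates[0][1].seed
    rng = np.random.default_rng(split_seed)
    n = data.n_samples
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    def subset(idx):
        return BinaryExpressionMatrix(
            values=data.values[idx],
            sample_ids=[data.sample_ids[i] for i in idx],
            feature_ids=list(data.feature_ids),
            mirna_index=data.mirna_index.copy(),
            mrna_index=data.mrna_index.copy(),
        )

    train, test = subset(train_idx), subset(test_idx)
    rows = []
    results = []
    for i, (arch, cfg, permute) in enumerate(candidates):
        fit_data = (
            permute_control(train, np.random.default_rng(split_seed + 1))
            if permute else train
        )
        res = MCadet(fit_data, arch).fit(cfg)
        results.append(res)
        rows.append({
            "candidate": i,
            "hidden_sizes": str(list(arch.hidden_sizes)),
            "use_causal_edges": arch.use_causal_edges,
            "sparsity_target": arch.sparsity_target,
            "permuted": permute,
            "train_error": res.reconstruction_error(fit_data),
            "heldout_error": res.reconstruction_error(test),
        })
    report = pd.DataFrame(rows)
    best = int(report["heldout_error"].idxmin())
    return best, report


# ---------------------------------------------------------------------
# serialization: deterministic single-file archive
# ---------------------------------------------------------------------

_MAGIC = b"MCADET1\n"


def _collect_arrays(results: MCadetResults) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}

    def add_layer(prefix: str, p: SemiRBMParams) -> None:
        arrays[f"{prefix}.W"] = p.W
        arrays[f"{prefix}.Pi"] = p.Pi
        arrays[f"{prefix}.bias_mrna"] = p.bias_mrna
        arrays[f"{prefix}.bias_mirna"] = p.bias_mirna
        arrays[f"{prefix}.bias_hidden"] = p.bias_hidden

    add_layer("layer0", results.bottom)
    for i, p in enumerate(results.upper_layers, start=1):
        add_layer(f"layer{i}", p)
    if results.autoencoder is not None:
        ae = results.autoencoder
        for i, (w, b, r, c) in enumerate(
            zip(ae.enc_W, ae.enc_b, ae.dec_R, ae.dec_c)
        ):
            arrays[f"ae.enc_W{i}"] = w
            arrays[f"ae.enc_b{i}"] = b
            arrays[f"ae.dec_R{i}"] = r
            arrays[f"ae.dec_c{i}"] = c
        arrays["ae.bias_mrna"] = ae.bias_mrna
        arrays["ae.bias_mirna"] = ae.bias_mirna
        arrays["ae.Pi"] = ae.Pi
    return arrays


def save_model(results: MCadetResults, path) -> None:
    """Single-file archive: a JSON metadata header followed by
    length-prefixed .npy payloads, byte-identical for identical fits."""
    arrays = _collect_arrays(results)
    data = results.model.data
    meta = {
        "format": "mcadet-model",
        "version": 1,
        "block_order": "mrna_first",
        "architecture": {
            "hidden_sizes": list(results.architecture.hidden_sizes),
            "use_causal_edges": results.architecture.use_causal_edges,
            "sparsity_target": results.architecture.sparsity_target,
            "sparsity_layers": results.architecture.sparsity_layers,
        },
        "config": asdict(results.config),
        "n_layers": 1 + len(results.upper_layers),
        "finetuned": results.autoencoder is not None,
        "sample_ids": list(data.sample_ids),
        "mrna_ids": data.mrna_ids,
        "mirna_ids": data.mirna_ids,
        "training_log": [list(t) for t in results.training_log],
        "finetune_log": [list(t) for t in results.finetune_log],
        "arrays": sorted(arrays),
    }
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        header = json.dumps(meta, sort_keys=True).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arrays[name]))
            payload = buf.getvalue()
            fh.write(len(payload).to_bytes(8, "little"))
            fh.write(payload)


def load_model(path) -> MCadetResults:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path} is not an mcadet model archive")
        hlen = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(hlen).decode())
        arrays = {}
        for name in meta["arrays"]:
            alen = int.from_bytes(fh.read(8), "little")
            arrays[name] = np.load(io.BytesIO(fh.read(alen)))

    def layer(prefix: str) -> SemiRBMParams:
        return SemiRBMParams(
            W=arrays[f"{prefix}.W"],
            Pi=arrays[f"{prefix}.Pi"],
            bias_mrna=arrays[f"{prefix}.bias_mrna"],
            bias_mirna=arrays[f"{prefix}.bias_mirna"],
            bias_hidden=arrays[f"{prefix}.bias_hidden"],
        )

    n_mrna = len(meta["mrna_ids"])
    n_mirna = len(meta["mirna_ids"])
    n_samples = len(meta["sample_ids"])
    placeholder = from_blocks(
        np.zeros((n_samples, n_mrna), dtype=np.int8),
        np.zeros((n_samples, n_mirna), dtype=np.int8),
        meta["sample_ids"], meta["mrna_ids"], meta["mirna_ids"],
    )
    arch = Architecture(**meta["architecture"])
    model = MCadet(placeholder, arch)
    ae = None
    if meta["finetuned"]:
        L = meta["n_layers"]
        ae = _Autoencoder(
            enc_W=[arrays[f"ae.enc_W{i}"] for i in range(L)],
            enc_b=[arrays[f"ae.enc_b{i}"] for i in range(L)],
            dec_R=[arrays[f"ae.dec_R{i}"] for i in range(L)],
            dec_c=[arrays[f"ae.dec_c{i}"] for i in range(L)],
            bias_mrna=arrays["ae.bias_mrna"],
            bias_mirna=arrays["ae.bias_mirna"],
            Pi=arrays["ae.Pi"],
        )
    return MCadetResults(
        model=model,
        bottom=layer("layer0"),
        upper_layers=[
            layer(f"layer{i}") for i in range(1, meta["n_layers"])
        ],
        config=TrainConfig(**meta["config"]),
        training_log=[tuple(t) for t in meta["training_log"]],
        autoencoder=ae,
        finetune_log=[tuple(t) for t in meta["finetune_log"]],
    )
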