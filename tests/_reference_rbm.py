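"""Independently coded vanilla binary RBM with CD-k.

Used as the oracle for the reduction property: a semi-RBM whose directed
miRNA->mRNA weights are identically zero (and excluded from updates) must
behave bit-for-bit like this implementation under a shared seed.  The
random-draw protocol is: one uniform block for the initial hidden sample,
then per CD round one (batch, n_visible) block for the visible sample and
— except after the final round — one (batch, n_hidden) block for the next
hidden sample.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def hidden_probs(v: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return expit(b + v @ W)


def visible_probs(h: np.ndarray, W: np.ndarray, a: np.ndarray) -> np.ndarray:
    return expit(a + h @ W.T)


def cd_gradients(
    v: np.ndarray,
    W: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    k: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batch-averaged CD-k statistics (data minus model)."""
    rng = np.random.default_rng(seed)
    s, n_visible = v.shape
    n_hidden = W.shape[1]
    ph = hidden_probs(v, W, b)
    h = (rng.random((s, n_hidden)) < ph).astype(float)
    for step in range(k):
        u_v = rng.random((s, n_visible))
        v_s = (u_v < visible_probs(h, W, a)).astype(float)
        ph_neg = hidden_probs(v_s, W, b)
        if step < k - 1:
            h = (rng.random((s, n_hidden)) < ph_neg).astype(float)
    dW = (v.T @ ph - v_s.T @ ph_neg) / s
    da = (v - v_s).mean(axis=0)
    db = (ph - ph_neg).mean(axis=0)
    return dW, da, db
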