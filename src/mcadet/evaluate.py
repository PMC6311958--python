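"""Interaction extraction, mechanism classification, the correlation
baseline, and benchmark scoring against a gold-standard pair list.

Predicted interactions come from the directed weight matrix Pi: for each
miRNA the mRNAs are ranked by absolute weight and the top 5% kept.  A
pair's mechanism is read off the fitted parameters — a strong Pi entry
means direct (causal) regulation, strong loadings of both RNAs on a
common hidden unit mean co-regulation by a shared regulator.  Scoring
follows the usual recall / positive-predictive-value / F1 conventions,
with a pooled two-proportion z-test to compare PPVs between methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import BinaryExpressionMatrix

__all__ = [
    "InteractionTable",
    "EvalReport",
    "extract_interactions",
    "classify_mechanism",
    "correlation_baseline",
    "score_predictions",
    "two_proportion_z",
    "overlap_counts",
    "pair_auroc",
]

log = logging.getLogger(__name__)


def _pi_and_ids(model, which: str):
    """Accept an MCadetResults or a (Pi, mirna_ids, mrna_ids) triple."""
    if isinstance(model, tuple):
        pi, mirna_ids, mrna_ids = model
        return np.asarray(pi, dtype=float), list(mirna_ids), list(mrna_ids)
    if which == "pretrained":
        pi = model.pi_pretrained
    elif which == "finetuned":
        pi = model.pi
    else:
        raise ValueError(f"unknown weight source {which!r}")
    data = model.model.data
    return np.asarray(pi, dtype=float), data.mirna_ids, data.mrna_ids


@dataclass
class InteractionTable:
    """Per-(miRNA, mRNA) signed weights with the top-fraction keep rule
    applied per miRNA."""

    table: pd.DataFrame  # mirna_id, mrna_id, weight, abs_rank, kept
    quantile: float

    def kept_pairs(self) -> set[tuple[str, str]]:
        kept = self.table[self.table["kept"]]
        return set(zip(kept["mirna_id"], kept["mrna_id"]))

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def extract_interactions(model, quantile: float = 0.05,
                         which: str = "finetuned") -> InteractionTable:
    """Rank mRNAs by |pi| within each miRNA; keep the top
    ceil(quantile * n_mrna).

    Ties are broken deterministically by larger |weight| first, then
    lexicographic mRNA ID.  ``model`` is an MCadetResults (whose causal
    edges must be enabled) or a raw (Pi, mirna_ids, mrna_ids) triple.
    """
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    if hasattr(model, "architecture") and not getattr(
        model.architecture, "use_causal_edges", True
    ):
        raise ValueError(
            "model was fitted without causal edges; no Pi to extract"
        )
    pi, mirna_ids, mrna_ids = _pi_and_ids(model, which)
    n_mrna = len(mrna_ids)
    n_keep = math.ceil(quantile * n_mrna)
    frames = []
    for k, mid in enumerate(mirna_ids):
        col = pi[:, k]
        order = sorted(
            range(n_mrna), key=lambda o: (-abs(col[o]), mrna_ids[o])
        )
        rank = np.empty(n_mrna, dtype=int)
        rank[order] = np.arange(1, n_mrna + 1)
        frames.append(pd.DataFrame({
            "mirna_id": mid,
            "mrna_id": mrna_ids,
            "weight": col,
            "abs_rank": rank,
            "kept": rank <= n_keep,
        }))
    table = pd.concat(frames, ignore_index=True)
    return InteractionTable(table=table, quantile=quantile)


def classify_mechanism(model, mirna_id: str, mrna_id: str,
                       causal_threshold: float | None = None,
                       loading_threshold: float | None = None,
                       interactions: InteractionTable | None = None) -> str:
    """Classify one pair as 'causal', 'confounded', 'both' or 'none'.

    Causal: |pi| reaches ``causal_threshold`` (default: membership in the
    per-miRNA top-5% kept set).  Confounded: both RNAs load on a common
    first-layer hidden unit with |W| >= ``loading_threshold`` (default:
    the 95th percentile of |W|).  ``interactions`` may carry a
    precomputed top-5% table to avoid re-ranking on repeated calls.
    """
    data = model.model.data
    try:
        k = data.mirna_ids.index(mirna_id)
    except ValueError:
        raise KeyError(f"unknown miRNA id {mirna_id!r}") from None
    try:
        o = data.mrna_ids.index(mrna_id)
    except ValueError:
        raise KeyError(f"unknown mRNA id {mrna_id!r}") from None

    pi = model.pi
    if causal_threshold is not None:
        causal = abs(pi[o, k]) >= causal_threshold
    else:
        if interactions is None:
            interactions = extract_interactions(model)
        causal = (mirna_id, mrna_id) in interactions.kept_pairs()

    W = model.bottom.W
    if loading_threshold is None:
        loading_threshold = float(np.quantile(np.abs(W), 0.95))
    n_mrna = model.bottom.n_mrna
    w_mr = np.abs(W[o])  # mRNA block rows come first
    w_mi = np.abs(W[n_mrna + k])
    confounded = bool(
        ((w_mr >= loading_threshold) & (w_mi >= loading_threshold)).any()
    )
    if causal and confounded:
        return "both"
    if causal:
        return "causal"
    if confounded:
        return "confounded"
    return "none"


def correlation_baseline(data: BinaryExpressionMatrix, alpha: float = 0.05
                         ) -> pd.DataFrame:
    """Pairwise linear regression of every mRNA on every miRNA with
    Benjamini-Hochberg FDR control across all pairs.

    Works on binary calls or continuous expression alike.  Returns one
    row per testable pair: slope, Pearson r, raw p, BH-adjusted q, and a
    ``retained`` flag (q <= alpha).  Constant features are skipped with a
    log entry.
    """
    n = data.n_samples
    if n < 3:
        raise ValueError("correlation baseline requires >= 3 samples")
    X = data.mirna_values.astype(float)
    Y = data.mrna_values.astype(float)
    sx = X.std(axis=0, ddof=1)
    sy = Y.std(axis=0, ddof=1)
    ok_x, ok_y = sx > 0, sy > 0
    for name, ok, ids in (("miRNA", ok_x, data.mirna_ids),
                          ("mRNA", ok_y, data.mrna_ids)):
        if not ok.all():
            skipped = [i for i, keep in zip(ids, ok) if not keep]
            log.info("skipping constant %s features: %s", name, skipped)
    Xc = (X[:, ok_x] - X[:, ok_x].mean(axis=0)) / sx[ok_x]
    Yc = (Y[:, ok_y] - Y[:, ok_y].mean(axis=0)) / sy[ok_y]
    r = (Xc.T @ Yc) / (n - 1)  # (n_mirna_ok, n_mrna_ok)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    slope = r * (sy[ok_y][None, :] / sx[ok_x][:, None])

    mirna_ids = [i for i, keep in zip(data.mirna_ids, ok_x) if keep]
    mrna_ids = [i for i, keep in zip(data.mrna_ids, ok_y) if keep]
    out = pd.DataFrame({
        "mirna_id": np.repeat(mirna_ids, len(mrna_ids)),
        "mrna_id": np.tile(mrna_ids, len(mirna_ids)),
        "slope": slope.ravel(),
        "r": r.ravel(),
        "p": p.ravel(),
    })
    if len(out):
        reject, q, _, _ = multipletests(
            out["p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )
        out["q"] = q
        out["retained"] = reject
    else:
        out["q"] = []
        out["retained"] = []
    return out


@dataclass
class EvalReport:
    """Benchmark of a prediction set against a gold standard."""

    tp: int
    fp: int
    fn: int
    recall: float
    ppv: float
    f1: float
    undefined: tuple[str, ...] = ()  # metrics with a zero denominator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "recall": self.recall, "ppv": self.ppv, "f1": self.f1,
            "undefined": ";".join(self.undefined),
        }])

    def to_text(self) -> str:
        lines = [
            "Prediction benchmark",
            f"  TP = {self.tp}   FP = {self.fp}   FN = {self.fn}",
            f"  recall (sensitivity)       = {self.recall:.4f}",
            f"  PPV (precision)            = {self.ppv:.4f}",
            f"  F1                         = {self.f1:.4f}",
        ]
        if self.undefined:
            lines.append(
                f"  zero-denominator metrics reported as 0: "
                f"{', '.join(self.undefined)}"
            )
        return "\n".join(lines)


def f1_score(recall: float, ppv: float) -> float:
    """Harmonic mean 2*recall*ppv/(recall+ppv); 0 when both are 0."""
    if recall + ppv == 0:
        return 0.0
    return 2.0 * recall * ppv / (recall + ppv)


def score_predictions(pred, gold, universe=None) -> EvalReport:
    """TP/FP/FN counts and recall/PPV/F1 of a predicted pair set.

    Pairs are (mirna_id, mrna_id) tuples; ``universe`` optionally
    restricts both sets (e.g. to mRNAs present in the expression data).
    Zero-denominator metrics are reported as 0 and flagged.
    """
    pred, gold = set(map(tuple, pred)), set(map(tuple, gold))
    if universe is not None:
        universe = set(map(tuple, universe))
        pred &= universe
        gold &= universe
    tp = len(pred & gold)
    fp = len(pred - gold)
    fn = len(gold - pred)
    undefined = []
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        undefined.append("recall")
    if tp + fp > 0:
        ppv = tp / (tp + fp)
    else:
        ppv = 0.0
        undefined.append("ppv")
    f1 = f1_score(recall, ppv)
    if recall + ppv == 0:
        undefined.append("f1")
    return EvalReport(tp=tp, fp=fp, fn=fn, recall=recall, ppv=ppv, f1=f1,
                      undefined=tuple(undefined))


def two_proportion_z(p1: float, n1: int, p2: float, n2: int
                     ) -> tuple[float, float]:
    """Pooled two-proportion z statistic and two-sided normal p-value.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (n1 p1 + n2 p2) / (n1 + n2).  A degenerate pooled proportion
    (0 or 1) yields z = +/-inf (0 if the difference is also 0).
    """
    for p in (p1, p2):
        if not (0 <= p <= 1):
            raise ValueError("proportions must lie in [0, 1]")
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    diff = p1 - p2
    if var == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p_value = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return z, p_value


def overlap_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for every region of the Venn diagram of >= 2 named sets.

    Keys are the sorted tuples of set names an element belongs to (the
    empty region is omitted); region counts sum to the size of the union.
    """
    if len(sets) < 2:
        raise ValueError("overlap_counts requires at least two sets")
    names = sorted(sets)
    counts: dict[tuple[str, ...], int] = {}
    for membership in product((False, True), repeat=len(names)):
        if not any(membership):
            continue
        region = set.union(*(set(sets[n])
                             for n, m in zip(names, membership) if m))
        for n, m in zip(names, membership):
            if m:
                region &= set(sets[n])
            else:
                region -= set(sets[n])
        key = tuple(n for n, m in zip(names, membership) if m)
        counts[key] = len(region)
    return counts


def pair_auroc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Area under the ROC curve of a score array against a boolean mask
    of true pairs (rank statistic, ties averaged)."""
    scores = np.asarray(scores, dtype=float).ravel()
    positives = np.asarray(positives, dtype=bool).ravel()
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both positive and negative pairs")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )
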