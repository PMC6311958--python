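"""Fold-change binarization of tumor expression against normal tissue.

Continuous tumor profiles are reduced to dysregulation calls by comparing
each feature to a per-feature summary of normal samples: a call of 1
means the tumor value differs from the normal reference by at least the
given fold (3-fold by default) in either direction.  The binarized miRNA
and mRNA matrices are then merged on shared samples into the single
matrix the model trains on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MIRNA, MRNA, BinaryExpressionMatrix

__all__ = [
    "ExpressionTable",
    "NormalReference",
    "build_reference",
    "binarize_fold_change",
    "merge_mirna_mrna",
]


@dataclass
class ExpressionTable:
    """Features x samples table of nonnegative expression values with a
    per-feature type label ('miRNA' or 'mRNA')."""

    values: pd.DataFrame
    feature_type: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("feature IDs are not unique")
        if self.values.columns.has_duplicates:
            # TCGA-style duplicate/triplicate samples: keep the first
            # occurrence after a deterministic sort
            df = self.values.sort_index(axis=1)
            self.values = df.loc[:, ~df.columns.duplicated(keep="first")]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.feature_type = self.feature_type.reindex(self.values.index)
        if self.feature_type.isna().any():
            missing = list(self.feature_type.index[self.feature_type.isna()])
            raise ValueError(f"features without a type label: {missing[:5]}")
        bad = ~self.feature_type.isin([MIRNA, MRNA])
        if bad.any():
            raise ValueError(
                f"unknown feature types: "
                f"{sorted(self.feature_type[bad].unique())}"
            )


@dataclass
class NormalReference:
    """Per-feature reference expression level (summary of normal samples
    plus a pseudocount), all strictly positive."""

    level: pd.Series
    pseudocount: float

    def __post_init__(self) -> None:
        if (self.level <= 0).any():
            raise ValueError("reference levels must be positive")


def build_reference(normals: ExpressionTable, summary: str = "median",
                    pseudocount: float = 1.0) -> NormalReference:
    """Summarise normal samples feature-by-feature (median by default)."""
    if normals.values.shape[1] < 1:
        raise ValueError("at least one normal sample is required")
    if normals.values.isna().all(axis=1).any():
        bad = list(
            normals.values.index[normals.values.isna().all(axis=1)]
        )
        raise ValueError(f"features with all-missing normals: {bad[:5]}")
    if summary == "median":
        level = normals.values.median(axis=1)
    elif summary == "mean":
        level = normals.values.mean(axis=1)
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return NormalReference(level=level + pseudocount, pseudocount=pseudocount)


def binarize_fold_change(tumors: ExpressionTable, ref: NormalReference,
                         fold: float = 3.0,
                         direction: str = "both") -> BinaryExpressionMatrix:
    """Call a feature dysregulated when its fold change versus the normal
    reference reaches ``fold`` (inclusive).

    direction 'up' flags only ratio >= fold, 'down' only ratio <= 1/fold,
    'both' (default) either.  The direction of each call is recorded in
    the returned matrix's ``sign`` attribute (+1 up, -1 down, 0 none).
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    level = ref.level.reindex(tumors.values.index)
    if level.isna().any():
        missing = list(level.index[level.isna()])
        raise ValueError(
            f"reference missing for features: {missing[:5]}"
        )
    ratio = (tumors.values + ref.pseudocount).div(level, axis=0)
    up = ratio.to_numpy() >= fold
    down = ratio.to_numpy() <= 1.0 / fold
    if direction == "up":
        calls = up
    elif direction == "down":
        calls = down
    else:
        calls = up | down
    sign = np.where(up & calls, 1, np.where(down & calls, -1, 0))
    types = tumors.feature_type.to_numpy()
    return BinaryExpressionMatrix(
        values=calls.T.astype(np.int8),
        sample_ids=list(tumors.values.columns.astype(str)),
        feature_ids=list(tumors.values.index.astype(str)),
        mirna_index=np.flatnonzero(types == MIRNA),
        mrna_index=np.flatnonzero(types == MRNA),
        sign=sign.T,
    )


def merge_mirna_mrna(mirna_bin: BinaryExpressionMatrix,
                     mrna_bin: BinaryExpressionMatrix
                     ) -> BinaryExpressionMatrix:
    """Inner-join the two binarized matrices on sample IDs.

    Output columns are the mRNA block followed by the miRNA block, and
    samples are ordered by sorted shared ID; every retained sample keeps
    its values unchanged."""
    shared = sorted(set(mirna_bin.sample_ids) & set(mrna_bin.sample_ids))
    if not shared:
        raise ValueError("no samples shared between the two matrices")

    def rows(m: BinaryExpressionMatrix) -> np.ndarray:
        pos = {s: i for i, s in enumerate(m.sample_ids)}
        return m.values[[pos[s] for s in shared]]

    mrna_vals = rows(mrna_bin)[:, mrna_bin.mrna_index]
    mirna_vals = rows(mirna_bin)[:, mirna_bin.mirna_index]
    n_mrna = mrna_vals.shape[1]
    return BinaryExpressionMatrix(
        values=np.hstack([mrna_vals, mirna_vals]),
        sample_ids=shared,
        feature_ids=mrna_bin.mrna_ids + mirna_bin.mirna_ids,
        mrna_index=np.arange(n_mrna),
        mirna_index=np.arange(n_mrna, n_mrna + mirna_vals.shape[1]),
    )
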