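"""Binary expression matrices and their on-disk text representation.

The model consumes a samples x features matrix of dysregulation calls
(0 = unchanged, 1 = dysregulated versus normal tissue), with the feature
set partitioned into a miRNA block and an mRNA block.  On disk a matrix is
a tab-separated table, features as rows (first column = feature ID, first
row = sample IDs), accompanied by a two-column feature-type sidecar
(feature_id, {miRNA|mRNA}) or an inline ``type`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIRNA = "miRNA"
MRNA = "mRNA"


class ShapeError(ValueError):
    """Array dimensions inconsistent with the model or data."""


@dataclass
class BinaryExpressionMatrix:
    """Samples x features 0/1 matrix partitioned into miRNA and mRNA blocks.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Binary dysregulation calls.
    sample_ids, feature_ids : sequences of unique identifiers.
    mirna_index, mrna_index : integer column indices of the two blocks;
        disjoint and jointly covering all columns.
    sign : optional ndarray matching ``values``
        Direction of dysregulation (+1 up, -1 down, 0 unchanged).
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    mirna_index: np.ndarray
    mrna_index: np.ndarray
    sign: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mirna_index = np.asarray(self.mirna_index, dtype=int)
        self.mrna_index = np.asarray(self.mrna_index, dtype=int)
        n_s, n_f = self.values.shape
        if len(self.sample_ids) != n_s:
            raise ShapeError(
                f"{len(self.sample_ids)} sample ids for {n_s} rows"
            )
        if len(self.feature_ids) != n_f:
            raise ShapeError(
                f"{len(self.feature_ids)} feature ids for {n_f} columns"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("sample_ids are not unique")
        if len(set(self.feature_ids)) != n_f:
            raise ValueError("feature_ids are not unique")
        both = np.concatenate([self.mirna_index, self.mrna_index])
        if len(np.unique(both)) != n_f or both.size != n_f:
            raise ValueError(
                "mirna_index and mrna_index must be disjoint and cover "
                f"all {n_f} columns"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must all be 0 or 1")

    # -- block views -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_mirna(self) -> int:
        return self.mirna_index.size

    @property
    def n_mrna(self) -> int:
        return self.mrna_index.size

    @property
    def mirna_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.mirna_index]

    @property
    def mrna_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.mrna_index]

    @property
    def mirna_values(self) -> np.ndarray:
        return self.values[:, self.mirna_index]

    @property
    def mrna_values(self) -> np.ndarray:
        return self.values[:, self.mrna_index]

    def canonical_values(self) -> np.ndarray:
        """Columns reordered to the model convention: mRNA block, then miRNA."""
        return np.ascontiguousarray(
            self.values[:, np.concatenate([self.mrna_index, self.mirna_index])]
        ).astype(float)

    def to_frame(self) -> pd.DataFrame:
        """Features x samples DataFrame (the on-disk orientation)."""
        return pd.DataFrame(
            self.values.T, index=self.feature_ids, columns=self.sample_ids
        )

    def feature_types(self) -> pd.Series:
        types = pd.Series(index=self.feature_ids, dtype=object, name="type")
        types.iloc[self.mirna_index] = MIRNA
        types.iloc[self.mrna_index] = MRNA
        return types


def from_blocks(
    mrna: np.ndarray,
    mirna: np.ndarray,
    sample_ids: list[str],
    mrna_ids: list[str],
    mirna_ids: list[str],
) -> BinaryExpressionMatrix:
    """Assemble a matrix from separate blocks, mRNA columns first."""
    values = np.hstack([np.asarray(mrna), np.asarray(mirna)])
    n_mrna = mrna.shape[1]
    return BinaryExpressionMatrix(
        values=values,
        sample_ids=list(sample_ids),
        feature_ids=list(mrna_ids) + list(mirna_ids),
        mrna_index=np.arange(n_mrna),
        mirna_index=np.arange(n_mrna, n_mrna + mirna.shape[1]),
    )


def read_matrix(path, types=None) -> BinaryExpressionMatrix:
    """Read a binary matrix from TSV (features x samples).

    ``types`` is either the path of a two-column sidecar (feature_id, type)
    or None, in which case the table must carry a ``type`` column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if types is not None:
        tmap = pd.read_csv(
            types, sep="\t", index_col=0, header=None, names=["feature", "type"]
        )["type"]
        ftype = tmap.reindex(df.index)
    elif "type" in df.columns:
        ftype = df.pop("type")
    else:
        raise ValueError(
            "feature types required: pass a sidecar file or include a "
            "'type' column"
        )
    if ftype.isna().any():
        missing = list(ftype.index[ftype.isna()])[:5]
        raise ValueError(f"features without a type annotation: {missing}")
    values = df.to_numpy().T
    ftype = ftype.astype(str)
    return BinaryExpressionMatrix(
        values=values.astype(np.int8),
        sample_ids=list(df.columns.astype(str)),
        feature_ids=list(df.index.astype(str)),
        mirna_index=np.flatnonzero(ftype.to_numpy() == MIRNA),
        mrna_index=np.flatnonzero(ftype.to_numpy() == MRNA),
    )


def write_matrix(matrix: BinaryExpressionMatrix, path, types_path=None) -> None:
    """Write a matrix as TSV plus (optionally) its feature-type sidecar."""
    matrix.to_frame().to_csv(path, sep="\t")
    if types_path is not None:
        matrix.feature_types().to_csv(types_path, sep="\t", header=False)
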