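"""TPM conversion and the initial expression filter.

TPM (transcripts per million) divides each gene's count by its length and
rescales every sample so the column sums to 10^6:

    TPM(g, s) = (count(g, s) / length(g)) / sum_g'(count(g', s) / length(g')) * 1e6

Genes enter the downstream cascade only if their mean TPM reaches the
threshold (default 1, inclusive) in at least one study group.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import GROUPS, StudyDesign
from .io import ExpressionMatrix

MatrixLike = Union[ExpressionMatrix, pd.DataFrame]


def tpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a counts matrix to TPM.

    Raises
    ------
    ValueError
        If the matrix is not counts, lacks lengths, or a sample has all-zero
        counts (TPM is undefined there).
    """
    if matrix.units != "counts":
        raise ValueError("tpm_normalize expects a counts matrix")
    if matrix.lengths is None:
        raise ValueError("tpm_normalize requires per-gene lengths")
    rate = matrix.values.div(matrix.lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        sample = totals.index[totals == 0][0]
        raise ValueError(f"sample {sample!r} has all-zero counts; TPM undefined")
    tpm = rate.div(totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, lengths=matrix.lengths, units="tpm")


class TPMNormalizer(TransformerMixin, BaseEstimator):
    """Transformer converting a genes x samples counts table to TPM.

    Rows are genes and columns are sequencing samples (the bulk RNA-seq
    matrix convention); normalization acts per column. Composes with
    sklearn pipelines operating on DataFrames.

    Parameters
    ----------
    lengths:
        Per-gene transcript length in bases, indexed like the input rows.
    """

    def __init__(self, lengths: pd.Series | None = None):
        self.lengths = lengths

    def fit(self, X: MatrixLike, y=None) -> "TPMNormalizer":
        matrix = self._as_matrix(X)
        self.lengths_ = matrix.lengths
        self.n_features_in_ = matrix.values.shape[1]
        return self

    def transform(self, X: MatrixLike) -> pd.DataFrame:
        return tpm_normalize(self._as_matrix(X)).values

    def _as_matrix(self, X: MatrixLike) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if self.lengths is None:
            raise ValueError("lengths are required when X is a plain DataFrame")
        return ExpressionMatrix(pd.DataFrame(X), lengths=self.lengths, units="counts")


def _tpm_frame(tpm: MatrixLike) -> pd.DataFrame:
    if isinstance(tpm, ExpressionMatrix):
        if tpm.units != "tpm":
            raise ValueError("expected a TPM-flagged matrix")
        return tpm.values
    return tpm


def group_means(tpm: MatrixLike, design: StudyDesign) -> pd.DataFrame:
    """Per-gene mean TPM within each of the four study groups."""
    values = _tpm_frame(tpm)
    cols = {}
    for group in GROUPS:
        samples = design.samples_in(group)
        if samples:
            cols[group] = values[samples].mean(axis=1)
    return pd.DataFrame(cols, index=values.index)


def expression_filter(
    tpm: MatrixLike,
    design: StudyDesign,
    min_tpm: float = 1.0,
    scope: str = "group_mean",
) -> tuple[pd.Index, pd.DataFrame]:
    """Select genes expressed at or above ``min_tpm`` in at least one group.

    Parameters
    ----------
    scope:
        ``"group_mean"`` keeps a gene if any group's mean TPM reaches the
        threshold (the default reading of expression "in any sample group");
        ``"any_sample"`` keeps a gene if any single sample reaches it.

    Returns
    -------
    (kept, means):
        Index of retained gene ids and the per-gene group-mean table for all
        genes (the filter is inclusive: ties at the threshold are kept).
    """
    values = _tpm_frame(tpm)
    if values.empty:
        raise ValueError("cannot filter an empty expression matrix")
    means = group_means(values, design)
    if scope == "group_mean":
        keep = (means >= min_tpm).any(axis=1)
    elif scope == "any_sample":
        keep = (values[design.sample_ids] >= min_tpm).any(axis=1)
    else:
        raise ValueError(f"unknown filter scope {scope!r}")
    return values.index[keep], means
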