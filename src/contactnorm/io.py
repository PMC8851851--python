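"""Readers and writers for the flat TSV formats used throughout the package.

All tables are tab-separated text with a header row:

* counts / TPM matrix — first column ``gene_id``, remaining columns samples;
* lengths — ``gene_id<TAB>length`` (bases);
* design — ``sample_id<TAB>group``;
* classification — the per-gene output of the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import StudyDesign, read_design

#: relative tolerance on the per-sample TPM column sum of 1e6
TPM_SUM_RTOL = 1e-6


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table.

    Parameters
    ----------
    values:
        Non-negative numeric table indexed by gene id, columns are sample
        ids. Counts may be non-integer (estimated counts are accepted).
    lengths:
        Per-gene length in bases, required when ``units == "counts"``.
    units:
        ``"counts"`` or ``"tpm"``. A TPM-flagged matrix must have every
        column summing to 1e6 within :data:`TPM_SUM_RTOL`.
    """

    values: pd.DataFrame
    lengths: Optional[pd.Series] = None
    units: str = "counts"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()]
            raise ValueError(f"duplicate gene id(s): {sorted(set(dup))[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()]
            raise ValueError(f"duplicate sample id(s): {sorted(set(dup))[:5]}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(f"missing value for gene {v.index[g]!r}, sample {v.columns[s]!r}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value for gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if self.units not in ("counts", "tpm"):
            raise ValueError(f"unknown units {self.units!r}; expected 'counts' or 'tpm'")
        if self.lengths is not None:
            lengths = self.lengths.reindex(v.index)
            if lengths.isna().any():
                missing = lengths.index[lengths.isna()][:5]
                raise ValueError(f"length missing for gene(s) {list(missing)}")
            if (lengths <= 0).any():
                bad = lengths.index[lengths <= 0][:5]
                raise ValueError(f"non-positive length for gene(s) {list(bad)}")
            self.lengths = lengths.astype(float)
        elif self.units == "counts":
            raise ValueError("a counts matrix requires per-gene lengths")
        if self.units == "tpm" and len(v.columns):
            sums = arr.sum(axis=0)
            off = np.abs(sums - 1e6) > TPM_SUM_RTOL * 1e6
            if off.any():
                s = v.columns[np.argmax(off)]
                raise ValueError(
                    f"TPM column {s!r} sums to {sums[np.argmax(off)]:.6g}, expected 1e6"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _read_table(path: str | Path, index_col: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != index_col:
        raise ValueError(
            f"{path}: first column must be {index_col!r}, got {frame.columns[0]!r}"
        )
    frame = frame.set_index(index_col)
    return frame


def read_counts(counts_path: str | Path, lengths_path: str | Path) -> ExpressionMatrix:
    """Read a counts matrix and its per-gene length table."""
    counts = _read_table(counts_path, "gene_id")
    for col in counts.columns:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        bad = coerced.isna() & counts[col].notna()
        if bad.any():
            gene = counts.index[bad][0]
            raise ValueError(
                f"{counts_path}: non-numeric value for gene {gene!r}, sample {col!r}"
            )
        counts[col] = coerced
    lengths_frame = _read_table(lengths_path, "gene_id")
    if "length" not in lengths_frame.columns:
        raise ValueError(f"{lengths_path}: expected a 'length' column")
    lengths = pd.to_numeric(lengths_frame["length"], errors="coerce")
    if lengths.isna().any():
        gene = lengths.index[lengths.isna()][0]
        raise ValueError(f"{lengths_path}: non-numeric length for gene {gene!r}")
    try:
        return ExpressionMatrix(counts, lengths=lengths, units="counts")
    except ValueError as err:
        raise ValueError(f"{counts_path}: {err}") from None


def read_expression(
    counts_path: str | Path,
    lengths_path: str | Path,
    design_path: str | Path,
) -> tuple[ExpressionMatrix, StudyDesign]:
    """Read and cross-validate the counts / lengths / design table trio.

    Sample order is harmonized: the matrix columns are reordered to match
    the design row order. Samples present in only one of the two files are
    reported by name.
    """
    matrix = read_counts(counts_path, lengths_path)
    design = read_design(design_path)
    matrix_samples = set(matrix.sample_ids)
    design_samples = set(design.sample_ids)
    missing = sorted(design_samples - matrix_samples)
    if missing:
        raise ValueError(
            f"{design_path}: sample(s) {missing} are in the design but not in {counts_path}"
        )
    extra = sorted(matrix_samples - design_samples)
    if extra:
        raise ValueError(
            f"{counts_path}: sample(s) {extra} have no group in {design_path}"
        )
    matrix.values = matrix.values[design.sample_ids]
    return matrix, design


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    out = lengths.rename("length").to_frame()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_classification(per_gene: pd.DataFrame, path: str | Path) -> None:
    out = per_gene.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
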