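"""Count-matrix I/O and low-count filtering.

The canonical on-disk layout is a genes x samples table: header row of
sample ids, first column of gene ids, tab- (``tsv``) or comma- (``csv``)
separated. A MatrixMarket triplet file plus two plain-text id files (one id
per line) is accepted as an equivalent sparse representation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from atmm.core import CountMatrix

__all__ = ["read_counts", "write_counts", "filter_low_counts"]

_SEPARATORS = {"tsv": "\t", "csv": ","}


def read_counts(
    path,
    format: str = "tsv",
    gene_ids_path=None,
    sample_ids_path=None,
) -> CountMatrix:
    """Read a validated count matrix.

    For ``format='mtx'`` the matrix is a MatrixMarket triplet file and
    ``gene_ids_path`` / ``sample_ids_path`` must name plain-text files with
    one identifier per line (rows and columns respectively).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in _SEPARATORS:
        frame = pd.read_csv(path, sep=_SEPARATORS[format], index_col=0)
        if frame.shape[0] == 0 or frame.shape[1] == 0:
            raise ValueError(f"{path}: empty count matrix")
        if frame.isna().any().any():
            gene = frame.index[np.where(frame.isna())[0][0]]
            raise ValueError(f"{path}: missing value in row {gene!r} (ragged table?)")
        for col in frame.columns:
            if not np.issubdtype(frame[col].dtype, np.number):
                raise ValueError(f"{path}: non-numeric entries in column {col!r}")
        values = frame.to_numpy()
        bad = np.argwhere((values < 0) | (values != np.round(values)))
        if len(bad):
            g, s = bad[0]
            raise ValueError(
                f"{path}: invalid count {values[g, s]!r} at gene "
                f"{frame.index[g]!r}, sample {frame.columns[s]!r}"
            )
        return CountMatrix(values, list(frame.index), list(frame.columns))
    if format == "mtx":
        if gene_ids_path is None or sample_ids_path is None:
            raise ValueError("mtx format needs gene_ids_path and sample_ids_path")
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        gene_ids = Path(gene_ids_path).read_text().split()
        sample_ids = Path(sample_ids_path).read_text().split()
        return CountMatrix(matrix, gene_ids, sample_ids)
    raise ValueError(f"unknown format {format!r} (expected tsv, csv or mtx)")


def write_counts(counts: CountMatrix, path, format: str = "tsv") -> None:
    """Write a count matrix as a genes x samples table."""
    if format not in _SEPARATORS:
        raise ValueError(f"unknown format {format!r} (expected tsv or csv)")
    frame = pd.DataFrame(
        counts.counts, index=list(counts.gene_ids), columns=list(counts.sample_ids)
    )
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=_SEPARATORS[format])


def filter_low_counts(
    counts: CountMatrix, min_count: int = 10, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with count >= ``min_count`` in at least ``min_samples`` samples.

    Gene order and the sample set are preserved. Raises if no gene survives.
    """
    keep = (counts.counts >= min_count).sum(axis=1) >= min_samples
    if not np.any(keep):
        raise ValueError(
            f"filter (min_count={min_count}, min_samples={min_samples}) "
            "removed every gene"
        )
    gene_ids = [g for g, flag in zip(counts.gene_ids, keep) if flag]
    return CountMatrix(counts.counts[keep], gene_ids, counts.sample_ids)
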