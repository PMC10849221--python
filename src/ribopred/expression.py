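"""Building the response variables: protein abundance (PA) and PA per mRNA.

Expression tables are pandas DataFrames indexed by gene id with one column
per replicate or condition; all values are non-negative abundances.  The
pipeline is: average replicates within each culture condition, quantile-
normalize the condition columns, average conditions into a single mRNA
value, then join with protein abundance and drop zero-expression genes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_replicates",
    "quantile_normalize",
    "build_response",
    "read_expression_table",
]


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression table (first column gene_id, one column per
    replicate/condition) into a gene-indexed DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression table")
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative expression values")
    return df.astype(float)


def aggregate_replicates(
    table: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Average replicate columns into one column per condition.

    ``grouping`` maps each column label to its condition.  Every column of
    the table must be assigned; missing cells (NaN) are excluded from the
    mean.  A condition with zero columns is an error.
    """
    missing = set(table.columns) - set(grouping)
    if missing:
        raise ValueError(f"columns with no condition assignment: {sorted(missing)}")
    conditions = sorted(set(grouping[c] for c in table.columns))
    out = {}
    for cond in conditions:
        cols = [c for c in table.columns if grouping[c] == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} has no replicate columns")
        out[cond] = table[cols].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=table.index)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalization across columns.

    Each column's k-th smallest value is replaced by the mean, across
    columns, of the k-th smallest values; per-column rank order is preserved
    and tied values within a column receive the mean of the reference values
    their ranks span (the "average ties" dialect).  After normalization
    every column holds the same multiset of values.
    """
    if table.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete columns")
    n = values.shape[0]
    # Reference distribution: mean of per-column sorted values.
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n)
        mapped[order] = reference
        # Average the reference values over each tie group.
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                mapped[order[i:k + 1]] = reference[i:k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def build_response(
    pa_table: pd.DataFrame, mrna_table: pd.DataFrame
) -> pd.DataFrame:
    """Join protein abundance with mRNA expression into the response table.

    ``pa_table`` must have a single (integrated) abundance column;
    ``mrna_table`` is the replicate-aggregated, quantile-normalized
    condition matrix, summarised per gene by the arithmetic mean over
    conditions.  Genes with zero PA or zero mRNA are removed.  Returns a
    DataFrame with columns ``pa``, ``mrna``, ``pa_per_mrna``.
    """
    if pa_table.shape[1] != 1:
        raise ValueError("pa_table must have exactly one column")
    pa = pa_table.iloc[:, 0].astype(float)
    mrna = mrna_table.mean(axis=1).astype(float)
    joined = pd.DataFrame({"pa": pa, "mrna": mrna}).dropna()
    joined = joined[(joined["pa"] > 0) & (joined["mrna"] > 0)]
    if joined.empty:
        raise ValueError("no genes shared between PA and mRNA tables")
    joined["pa_per_mrna"] = joined["pa"] / joined["mrna"]
    return joined
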