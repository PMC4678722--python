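"""Expression-matrix ingestion, filtering, transformation and partitioning.

An expression matrix is represented throughout the package as a pandas
DataFrame with gene identifiers as the index (rows) and sample identifiers
as the columns, holding log-scale expression values.  ``validate_expression``
enforces the contract: unique gene and sample identifiers, purely numeric
values, and no missing entries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "validate_expression",
    "read_expression",
    "write_expression",
    "quantile_filter",
    "minmax_scale",
    "log_transform",
    "train_test_split",
]


@dataclass(frozen=True)
class FilterParams:
    """Low-expression filter: keep genes whose per-gene ``quantile`` of
    expression is at least ``cutoff``.

    The defaults (90th quantile, cutoff 5) target the low mode of the
    bimodal quantile distribution typical of log-scale tumor array data.
    """

    quantile: float = 0.90
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")


def _find_duplicates(values) -> list:
    seen: set = set()
    dups: list = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen.add(v)
    return dups


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract and return the frame unchanged.

    Raises ``ValueError`` naming the offending gene/sample/cell on duplicate
    identifiers, non-numeric values, or missing entries.
    """
    dup_genes = _find_duplicates(expr.index)
    if dup_genes:
        raise ValueError(f"duplicate gene identifier(s): {', '.join(map(str, dup_genes))}")
    dup_samples = _find_duplicates(expr.columns)
    if dup_samples:
        raise ValueError(f"duplicate sample identifier(s): {', '.join(map(str, dup_samples))}")

    numeric = expr.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & expr.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {expr.iat[i, j]!r} at gene {expr.index[i]!r}, "
            f"sample {expr.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    out = numeric.astype(float)
    out.index = out.index.astype(str)
    out.index.name = "gene"
    out.columns = out.columns.astype(str)
    return out


def read_expression(path: str, format: str = "tsv") -> pd.DataFrame:
    """Read a genes × samples expression matrix from ``tsv`` or ``gct`` (1.2).

    TSV: tab-delimited, header row of sample ids, first column of gene ids.
    GCT 1.2: ``#1.2`` version line, a dimensions line, then a table whose
    first two columns are Name and Description.
    """
    if format == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"unsupported GCT version line: {version!r}")
            dims = fh.readline().split()
            n_rows, n_cols = int(dims[0]), int(dims[1])
            raw = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col=0, dtype=object)
        raw = raw.drop(columns=raw.columns[0])  # Description column
        if raw.shape != (n_rows, n_cols):
            raise ValueError(
                f"GCT header declares {(n_rows, n_cols)} but table is {raw.shape}"
            )
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'gct')")
    return validate_expression(raw)


def write_expression(expr: pd.DataFrame, path: str, format: str = "tsv") -> None:
    """Write an expression matrix as TSV or GCT 1.2."""
    if format == "tsv":
        expr.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            body = expr.copy()
            body.insert(0, "Description", expr.index)
            body.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown format {format!r}")


def quantile_filter(
    expr: pd.DataFrame, params: FilterParams = FilterParams()
) -> tuple[pd.DataFrame, pd.Series]:
    """Drop genes expressed at a low level or not at all.

    A gene is retained iff its per-gene quantile (linear-interpolation /
    "type 7" convention, the default of most analysis environments) at
    ``params.quantile`` is >= ``params.cutoff``.  Returns the filtered
    matrix and the per-gene quantile values for reporting.
    """
    if expr.shape[1] < 2:
        raise ValueError("quantile_filter requires at least 2 samples")
    q = np.quantile(expr.to_numpy(), params.quantile, axis=1, method="linear")
    quantiles = pd.Series(q, index=expr.index, name=f"q{params.quantile:g}")
    keep = quantiles >= params.cutoff
    if not keep.any():
        raise ValueError(
            f"no gene passes the filter (quantile {params.quantile:g} >= "
            f"{params.cutoff:g}); the cutoff is too strict for these data"
        )
    return expr.loc[keep], quantiles


def minmax_scale(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's expression vector linearly onto [0, 1].

    Scaling is per gene within the given dataset.  Constant genes have no
    defined scaling and are rejected; they should have been removed by
    ``quantile_filter`` / upstream eligibility restriction.
    """
    values = expr.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    flat = (hi - lo).ravel() == 0
    if flat.any():
        gene = expr.index[np.flatnonzero(flat)[0]]
        raise ValueError(f"constant gene {gene!r} cannot be min-max scaled")
    return pd.DataFrame((values - lo) / (hi - lo), index=expr.index, columns=expr.columns)


def log_transform(
    expr: pd.DataFrame, base: float = 2.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Element-wise log(x + pseudocount) for count-scale (RNA-seq) input.

    Base 2 with pseudocount 1 by default, so zero counts map to zero.
    """
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value {values[i, j]} at gene {expr.index[i]!r}, "
            f"sample {expr.columns[j]!r}; log transform expects counts >= 0"
        )
    out = np.log(values + pseudocount) / np.log(base)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def train_test_split(
    expr: pd.DataFrame, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomly partition samples into disjoint training/testing matrices.

    Train size is ``round(train_fraction * n_samples)``.  Samples are
    shuffled by a seeded RNG, then each partition keeps the original column
    order.  No stratification.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = expr.shape[1]
    if n < 3:
        raise ValueError("train_test_split requires at least 3 samples")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return expr.iloc[:, train_idx], expr.iloc[:, test_idx]
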