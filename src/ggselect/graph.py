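"""Co-expression graph construction: correlation, thresholding, eligibility.

The gene co-expression graph G = (V, E) is held as a dense symmetric binary
adjacency matrix (a genes × genes DataFrame of 0/1 with zero diagonal): an
edge joins two genes whose absolute Pearson correlation meets the threshold.
Space is O(n²) by construction, matching the dense workflow the selection
algorithm assumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "pearson_matrix",
    "binarize",
    "degrees",
    "eligible_genes",
    "restrict_to_eligible",
    "component_summary",
    "write_matrix",
    "read_matrix",
]


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of all gene pairs across samples.

    Returns a symmetric genes × genes DataFrame with unit diagonal.
    Constant genes have undefined correlation and are rejected.
    """
    if expr.shape[1] < 3:
        raise ValueError("pearson_matrix requires at least 3 samples")
    values = expr.to_numpy(dtype=float)
    flat = values.std(axis=1) == 0
    if flat.any():
        gene = expr.index[np.flatnonzero(flat)[0]]
        raise ValueError(f"constant gene {gene!r} has undefined correlation")
    r = np.corrcoef(values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def binarize(corr: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Threshold |r| to a binary adjacency matrix.

    edge(i, j) = 1 iff i != j and |r[i, j]| >= threshold; ties at exactly
    the threshold are edges. The diagonal is forced to zero.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    adj = (np.abs(corr.to_numpy()) >= threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


def degrees(adj: pd.DataFrame) -> pd.Series:
    """Per-gene degree (row sums of the adjacency matrix)."""
    return pd.Series(
        adj.to_numpy().sum(axis=1).astype(int), index=adj.index, name="degree"
    )


def eligible_genes(adj: pd.DataFrame, redundancy: int = 1) -> pd.Index:
    """Genes correlated to at least ``redundancy`` other genes.

    These are the genes that can serve as directly measured (DM) genes or
    be predicted.  Eligibility is computed once, on the full adjacency:
    degrees are not recomputed after removing ineligible genes.
    """
    if redundancy < 1:
        raise ValueError(f"redundancy must be >= 1, got {redundancy}")
    deg = degrees(adj)
    return adj.index[deg >= redundancy]


def restrict_to_eligible(adj: pd.DataFrame, redundancy: int = 1) -> pd.DataFrame:
    """Adjacency restricted to the eligible × eligible sub-matrix."""
    keep = eligible_genes(adj, redundancy)
    return adj.loc[keep, keep]


def component_summary(
    adj: pd.DataFrame, include_isolated: bool = False
) -> tuple[list[int], float]:
    """Connected-component sizes (descending) and mean degree.

    Isolated vertices are excluded from both the size list and the mean
    degree unless ``include_isolated`` is set.
    """
    a = adj.to_numpy()
    deg = a.sum(axis=1)
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    if not include_isolated:
        isolated_labels = set(labels[deg == 0])
        sizes = np.array([s for lab, s in enumerate(sizes) if lab not in isolated_labels])
        deg = deg[deg > 0]
    mean_degree = float(deg.mean()) if deg.size else 0.0
    return sorted((int(s) for s in sizes), reverse=True), mean_degree


def write_matrix(mat: pd.DataFrame, path: str, as_int: bool = False) -> None:
    """Serialize a square gene × gene matrix as TSV (gene ids as header and
    first column)."""
    out = mat.astype(int) if as_int else mat
    out.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path: str) -> pd.DataFrame:
    """Read a square gene × gene matrix written by :func:`write_matrix`."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    mat.columns = mat.columns.astype(str)
    if list(mat.index) != list(mat.columns):
        raise ValueError("matrix row and column identifiers differ")
    return mat
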