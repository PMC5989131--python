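"""Count-matrix handling for community comparison.

A count matrix is a pandas DataFrame with feature rows (taxa or functional
genes) and sample columns.  Samples are made comparable by scaling every
column to the smallest column total, optionally square-root or
presence/absence transformed, and compared by Bray-Curtis or Jaccard
dissimilarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "normalize_to_smallest",
    "subsample_to_smallest",
    "transform",
    "distance",
    "prevalence_filter",
    "hierarchical_cluster",
]


def _check_matrix(m: pd.DataFrame) -> None:
    if (m.values < 0).any():
        raise ValueError("count matrix contains negative entries")


def normalize_to_smallest(m: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column so all totals equal the smallest total.

    Fractional scaling (no re-rounding), so within-column proportions are
    preserved exactly.
    """
    _check_matrix(m)
    totals = m.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0][0]
        raise ValueError(f"sample {empty!r} has zero total count")
    return m * (totals.min() / totals)


def subsample_to_smallest(m: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Seeded multinomial alternative to fractional normalization.

    Each column is resampled down to the smallest column total by drawing
    without replacement from its reads (multivariate hypergeometric).
    """
    _check_matrix(m)
    counts = m.round().astype(np.int64)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("cannot subsample an empty sample")
    depth = int(totals.min())
    rng = np.random.default_rng(seed)
    out = {}
    for col in counts.columns:
        out[col] = rng.multivariate_hypergeometric(counts[col].values, depth)
    return pd.DataFrame(out, index=m.index, dtype=float)


def transform(m: pd.DataFrame, method: str) -> pd.DataFrame:
    """Element-wise transform: ``sqrt`` or ``presence`` (0/1)."""
    _check_matrix(m)
    if method == "sqrt":
        return np.sqrt(m)
    if method == "presence":
        return (m > 0).astype(float)
    raise ValueError(f"unknown transform {method!r}")


def distance(m: pd.DataFrame, method: str = "braycurtis") -> DistanceMatrix:
    """Pairwise sample dissimilarity.

    braycurtis: sum|x-y| / sum(x+y) on the columns as given; jaccard: on
    presence/absence, 1 - |intersection|/|union|.  A pair of all-zero
    columns is defined to have distance 0 (with a warning) so downstream
    network construction stays valid.
    """
    _check_matrix(m)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    x = m.values.astype(float)
    if method == "braycurtis":
        num = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
        den = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    elif method == "jaccard":
        b = x > 0
        inter = (b[:, :, None] & b[:, None, :]).sum(axis=0)
        union = (b[:, :, None] | b[:, None, :]).sum(axis=0)
        num, den = union - inter, union
    else:
        raise ValueError(f"unknown distance method {method!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    if (den == 0).any() and m.shape[1] > 1:
        both_zero = (den == 0) & ~np.eye(m.shape[1], dtype=bool)
        if both_zero.any():
            warnings.warn("sample pair(s) with no observations: distance set to 0")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(d, ids=[str(c) for c in m.columns])


def prevalence_filter(m: pd.DataFrame, min_frac: float = 0.5) -> pd.DataFrame:
    """Keep rows present (value > 0) in at least ceil(min_frac * n) samples."""
    _check_matrix(m)
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    need = int(np.ceil(min_frac * m.shape[1]))
    keep = (m > 0).sum(axis=1) >= need
    if not keep.any():
        warnings.warn("prevalence filter removed every row")
    return m.loc[keep]


def hierarchical_cluster(m: pd.DataFrame, linkage_method: str = "average",
                         metric: str = "braycurtis"):
    """Average-linkage clustering of the matrix rows.

    Rows are compared by Bray-Curtis distance (ties broken deterministically
    by the lexicographic row order of the input).  Returns ``(row_order,
    linkage_matrix)`` where ``row_order`` is the dendrogram leaf ordering of
    the row labels and ``linkage_matrix`` is in scipy format.
    """
    _check_matrix(m)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    m = m.sort_index()
    dt = distance(m.T, method=metric)  # rows as "samples"
    z = hierarchy.linkage(squareform(dt.data, checks=False), method=linkage_method)
    order = [m.index[i] for i in hierarchy.leaves_list(z)]
    return order, z
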