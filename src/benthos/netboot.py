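"""Bootstrap reproducibility of split networks.

Reads are resampled with replacement from each sample's genus-level
annotations, a Bray-Curtis neighbor-net splits graph is rebuilt per
iteration, shortest paths between the sample nodes are extracted, and the
resulting distances are decomposed into within- and between-group
components after Gower and Krzanowski:

    T = (1/n) sum_{i<j} d_ij^2
    W = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    B = T - W

The identity T = W + B holds exactly for every distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from . import neighbornet, profiles

__all__ = [
    "BootstrapConfig",
    "bootstrap_subsample",
    "bootstrap_networks",
    "group_distance_decomposition",
    "summarize_iterations",
]


@dataclass
class BootstrapConfig:
    """Bootstrap settings.

    ``n_reads`` is the per-sample resampling depth.  The study-scale value
    is six million reads per sample; the desk-scale default is 10,000.
    """
    n_iter: int = 100
    n_reads: int = 10_000
    grouping: str = "land_use"
    seed: int = 0
    total_pool: bool = False  # resample one pooled read multiset instead
    weighted_paths: bool = True

    def __post_init__(self):
        if self.n_iter < 1 or self.n_reads < 1:
            raise ValueError("n_iter and n_reads must be >= 1")


def bootstrap_subsample(m: pd.DataFrame, n_reads: int, seed: int,
                        total_pool: bool = False) -> pd.DataFrame:
    """Resample ``n_reads`` reads with replacement per sample.

    Each column is replaced by a multinomial draw with probabilities equal
    to its observed feature proportions, so every resampled column totals
    exactly ``n_reads``.  With ``total_pool`` the proportions come from the
    pooled read multiset of all samples.
    """
    totals = m.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0][0]
        raise ValueError(f"sample {empty!r} has no annotated reads")
    rng = np.random.default_rng(seed)
    out = {}
    pooled = m.sum(axis=1) / m.values.sum() if total_pool else None
    for col in m.columns:
        p = pooled.values if total_pool else (m[col] / totals[col]).values
        out[col] = rng.multinomial(n_reads, p)
    return pd.DataFrame(out, index=m.index, dtype=float)


def group_distance_decomposition(dm: DistanceMatrix, groups) -> dict:
    """Gower-Krzanowski within/between decomposition of squared distances.

    Also reports the mean raw (unsquared) within- and between-group
    pairwise distances.
    """
    groups = pd.Series(list(groups), index=list(dm.ids))
    labels = groups.unique()
    d = dm.data
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    d2 = d ** 2
    T = float(d2[iu].sum() / n)
    W = 0.0
    W_g = {}
    within_mask = np.zeros((n, n), dtype=bool)
    gvals = groups.values
    for lab in labels:
        idx = np.flatnonzero(gvals == lab)
        ng = idx.size
        sub = d2[np.ix_(idx, idx)]
        wg = float(np.triu(sub, k=1).sum() / ng)
        W_g[str(lab)] = wg
        W += wg
        within_mask[np.ix_(idx, idx)] = True
    B = T - W
    within_pairs = within_mask[iu]
    mean_within = float(d[iu][within_pairs].mean()) if within_pairs.any() else 0.0
    between = ~within_pairs
    mean_between = float(d[iu][between].mean()) if between.any() else 0.0
    return {"T": T, "W": W, "B": B, "W_g": W_g,
            "mean_within": mean_within, "mean_between": mean_between}


def bootstrap_networks(m: pd.DataFrame, groups, cfg: BootstrapConfig,
                       keep_graphs: bool = False):
    """Resample-and-rebuild network bootstrap.

    Per iteration: multinomial read resample, Bray-Curtis distances,
    neighbor-net splits graph, shortest-path submatrix over the sample
    nodes, and the group-distance decomposition of that submatrix.

    Returns ``(per_iteration_table, submatrices, graphs)``; ``graphs`` is
    empty unless ``keep_graphs``.
    """
    groups = pd.Series(list(groups), index=[str(c) for c in m.columns])
    rows = []
    submatrices = []
    graphs = []
    for it in range(cfg.n_iter):
        boot = bootstrap_subsample(m, cfg.n_reads, seed=cfg.seed + it,
                                   total_pool=cfg.total_pool)
        try:
            dm = profiles.distance(boot, "braycurtis")
            css = neighbornet.neighbor_net(dm)
            graph = neighbornet.build_splits_graph(css)
            sub = neighbornet.graph_distance_submatrix(
                graph, ids=[str(c) for c in m.columns],
                weighted=cfg.weighted_paths)
        except Exception as exc:  # noqa: BLE001 - annotate iteration
            raise RuntimeError(f"bootstrap iteration {it} failed: {exc}") from exc
        dec = group_distance_decomposition(sub, groups.loc[list(sub.ids)])
        rows.append({"iteration": it, "n_nodes": graph.number_of_nodes(),
                     **{k: dec[k] for k in ("T", "W", "B",
                                            "mean_within", "mean_between")},
                     **{f"W_{g}": v for g, v in dec["W_g"].items()}})
        submatrices.append(sub)
        if keep_graphs:
            graphs.append(graph)
    return pd.DataFrame(rows), submatrices, graphs


def summarize_iterations(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/sd summary of the per-iteration decomposition table."""
    cols = [c for c in table.columns if c != "iteration"]
    return pd.DataFrame({"mean": table[cols].mean(),
                         "sd": table[cols].std(ddof=1)})
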