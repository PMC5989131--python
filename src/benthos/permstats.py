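"""Permutational multivariate statistics for crossed factorial designs.

PERMANOVA partitions a distance matrix by a balanced crossed design
(fixed and random factors), builds pseudo-F ratios from the expected mean
squares of the mixed model, computes p-values by Freedman-Lane permutation
of reduced-model residuals, and pools non-significant interactions
(P > 0.25) into their denominator.  PERMDISP tests homogeneity of
multivariate dispersion via distances to group centroids in the
principal-coordinate geometry (negative eigenvalues retained through the
Gower kernel).  SIMPER decomposes average between-group Bray-Curtis
dissimilarity by feature, and RELATE correlates two distance matrices by
Spearman rank with a Mantel-type permutation test.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "gower_center",
    "permanova",
    "permdisp",
    "simper",
    "relate",
]


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = -1/2 J D^2 J with J = I - 11'/n."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _averaging_matrix(labels: np.ndarray) -> np.ndarray:
    """Projector that replaces each value by its group mean."""
    n = labels.size
    m = np.zeros((n, n))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        m[np.ix_(idx, idx)] = 1.0 / idx.size
    return m


def _term_projectors(metadata: pd.DataFrame, factors: list[str]):
    """Balanced-design ANOVA projectors for every main effect/interaction.

    P_T = sum_{S subseteq T} (-1)^{|T|-|S|} M_S, with M_S the cell-mean
    averaging projector over the factor combination S.  Requires a
    balanced fully crossed design.
    """
    n = len(metadata)
    levels = {f: np.unique(metadata[f].values) for f in factors}
    cells = metadata.groupby(factors, observed=True).size()
    expected_cells = int(np.prod([len(levels[f]) for f in factors]))
    if len(cells) != expected_cells or cells.nunique() != 1:
        raise ValueError("design must be balanced and fully crossed")
    if any(len(levels[f]) < 2 for f in factors):
        raise ValueError("every factor needs at least 2 levels")

    M: dict[frozenset, np.ndarray] = {frozenset(): np.ones((n, n)) / n}
    for k in range(1, len(factors) + 1):
        for S in combinations(factors, k):
            key = metadata[list(S)].astype(str).agg("|".join, axis=1).values
            M[frozenset(S)] = _averaging_matrix(key)

    projectors: dict[tuple, np.ndarray] = {}
    dfs: dict[tuple, int] = {}
    for k in range(1, len(factors) + 1):
        for T in combinations(factors, k):
            P = np.zeros((n, n))
            for sz in range(len(T) + 1):
                for S in combinations(T, sz):
                    P += (-1) ** (len(T) - sz) * M[frozenset(S)]
            projectors[T] = P
            dfs[T] = int(np.prod([len(levels[f]) - 1 for f in T]))
    resid = np.eye(n) - M[frozenset(factors)]
    df_resid = n - expected_cells
    return projectors, dfs, resid, df_resid


def _denominator(term: tuple, random_factors: set, all_terms: list[tuple]):
    """EMS denominator: a purely fixed term is tested against its
    interaction with the random factor; every random-containing term is
    tested against the residual."""
    if random_factors and not (set(term) & random_factors):
        wider = tuple(sorted(set(term) | random_factors))
        for t in all_terms:
            if set(t) == set(wider):
                return t
    return "Residual"


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame,
              factors: list[str], random_factors: list[str] | None = None,
              n_perm: int = 9999, pool_threshold: float = 0.25,
              seed: int = 0, exhaustive: bool = False) -> pd.DataFrame:
    """Mixed-design PERMANOVA with reduced-model permutation and pooling.

    Parameters
    ----------
    dm : distance matrix; its ids must index ``metadata``.
    factors : crossed design factors (columns of ``metadata``); all main
        effects and interactions are fitted.
    random_factors : subset of ``factors`` treated as random (at most one).
    n_perm : permutations per term (ignored when ``exhaustive``).
    pool_threshold : interactions with p above this are pooled into the
        residual, highest order first, and the table is recomputed;
        ``None`` disables pooling.
    exhaustive : enumerate all n! sample permutations (small n only).

    Returns an ANOVA-style table with one row per term plus Residual and
    Total.
    """
    random_set = set(random_factors or [])
    if not random_set <= set(factors):
        raise ValueError("random_factors must be a subset of factors")
    if len(random_set) > 1:
        raise ValueError("at most one random factor is supported")
    meta = metadata.loc[list(dm.ids)]
    projectors, dfs, resid_proj, df_resid = _term_projectors(meta, list(factors))
    g = gower_center(dm.data)
    n = g.shape[0]
    rng = np.random.default_rng(seed)

    if exhaustive:
        perms = [np.array(p) for p in permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    def fit(model_terms: list[tuple], pooled: list[tuple]):
        """SS/MS/F/p table for the given model; pooled terms are folded
        into the residual."""
        resid = resid_proj.copy()
        df_res = df_resid
        for t in pooled:
            resid = resid + projectors[t]
            df_res += dfs[t]
        ss = {t: float(np.sum(projectors[t] * g.T)) for t in model_terms}
        ss_res = float(np.sum(resid * g.T))
        ms = {t: ss[t] / dfs[t] for t in model_terms}
        ms_res = ss_res / df_res if df_res > 0 else np.nan

        rows = {}
        for t in model_terms:
            den = _denominator(t, random_set, model_terms)
            ms_den = ms_res if den == "Residual" else ms[den]
            f_obs = ms[t] / ms_den if ms_den > 0 else np.inf

            # Freedman-Lane: permute residuals of the model without t
            reduced = np.zeros((n, n))
            for t2 in model_terms:
                if t2 != t:
                    reduced += projectors[t2]
            r_red = np.eye(n) - np.ones((n, n)) / n - reduced
            g_res = r_red @ g @ r_red
            p_den = resid if den == "Residual" else projectors[den]
            df_den = df_res if den == "Residual" else dfs[den]
            count = 0
            for pi in perms:
                gp = g_res[np.ix_(pi, pi)]
                ss_t = float(np.sum(projectors[t] * gp.T))
                ss_d = float(np.sum(p_den * gp.T))
                f_star = (ss_t / dfs[t]) / (ss_d / df_den) if ss_d > 0 else np.inf
                if f_star >= f_obs - 1e-12:
                    count += 1
            if exhaustive:
                p = count / len(perms)
            else:
                p = (1 + count) / (len(perms) + 1)
            rows[t] = {"df": dfs[t], "SS": ss[t], "MS": ms[t],
                       "pseudo_F": f_obs, "p": p,
                       "denominator": "Residual" if den == "Residual"
                       else " x ".join(den)}
        return rows, ss_res, df_res, ms_res

    all_terms = sorted(projectors, key=lambda t: (len(t), t))
    model_terms = list(all_terms)
    pooled: list[tuple] = []
    # iterative pooling: highest-order interactions first, one sweep per
    # order; pool_threshold=None disables pooling altogether
    max_order = max(len(t) for t in all_terms) if pool_threshold is not None else 1
    for order in range(max_order, 1, -1):
        rows, *_ = fit(model_terms, pooled)
        drop = [t for t in model_terms
                if len(t) == order and rows[t]["p"] > pool_threshold]
        if drop:
            pooled.extend(drop)
            model_terms = [t for t in model_terms if t not in drop]

    rows, ss_res, df_res, _ = fit(model_terms, pooled)
    out = []
    for t in all_terms:
        name = " x ".join(t)
        if t in model_terms:
            out.append({"term": name, **rows[t], "pooled": False})
        else:
            out.append({"term": name, "df": dfs[t], "SS": np.nan, "MS": np.nan,
                        "pseudo_F": np.nan, "p": np.nan, "denominator": "",
                        "pooled": True})
    total_ss = float(np.trace(g))
    out.append({"term": "Residual", "df": df_res, "SS": ss_res,
                "MS": ss_res / df_res if df_res else np.nan,
                "pseudo_F": np.nan, "p": np.nan, "denominator": "",
                "pooled": False})
    out.append({"term": "Total", "df": n - 1, "SS": total_ss, "MS": np.nan,
                "pseudo_F": np.nan, "p": np.nan, "denominator": "",
                "pooled": False})
    return pd.DataFrame(out).set_index("term")


def _dist_to_centroids(g: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Squared distance of each sample to its group centroid, computed in
    the principal-coordinate geometry via the Gower kernel (negative
    eigenvalues enter with their sign, per Anderson's method)."""
    n = g.shape[0]
    z2 = np.empty(n)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        ng = idx.size
        gsub = g[np.ix_(idx, idx)]
        row = g[np.ix_(idx, idx)].sum(axis=1)
        mean_all = gsub.sum() / ng ** 2
        for pos, i in enumerate(idx):
            z2[i] = g[i, i] - 2 * row[pos] / ng + mean_all
    return z2


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 9999,
             seed: int = 0) -> dict:
    """Permutation test of homogeneity of multivariate dispersions.

    Returns F, p, and the per-group mean distance to centroid.
    """
    groups = pd.Series(list(groups), index=list(dm.ids))
    labels = groups.values
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    g = gower_center(dm.data)
    z = np.sqrt(np.maximum(_dist_to_centroids(g, labels), 0.0))

    def anova_f(vals: np.ndarray, labs: np.ndarray) -> float:
        grand = vals.mean()
        ssb = ssw = 0.0
        for lab in uniq:
            v = vals[labs == lab]
            ssb += v.size * (v.mean() - grand) ** 2
            ssw += ((v - v.mean()) ** 2).sum()
        dfb, dfw = len(uniq) - 1, vals.size - len(uniq)
        if ssw == 0:
            return math.inf if ssb > 0 else 0.0
        return (ssb / dfb) / (ssw / dfw)

    f_obs = anova_f(z, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        pi = rng.permutation(len(labels))
        zp = np.sqrt(np.maximum(_dist_to_centroids(g, labels[pi]), 0.0))
        # distances recomputed under the permuted grouping
        if anova_f(zp, labels[pi]) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    means = {str(lab): float(z[labels == lab].mean()) for lab in uniq}
    return {"F": float(f_obs), "p": float(p), "group_mean_dispersion": means}


def simper(m: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-feature decomposition of average between-group Bray-Curtis.

    For each between-group sample pair the feature contribution is
    |x_ij - x_ik| / sum_i (x_ij + x_ik); contributions are averaged over
    pairs and sum to the mean between-group Bray-Curtis dissimilarity.
    """
    groups = pd.Series(list(groups), index=[str(c) for c in m.columns])
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("SIMPER requires exactly two groups")
    a_cols = [c for c in m.columns if groups[str(c)] == levels[0]]
    b_cols = [c for c in m.columns if groups[str(c)] == levels[1]]
    if not a_cols or not b_cols:
        raise ValueError("both groups must be non-empty")
    x = m.values.astype(float)
    ia = [m.columns.get_loc(c) for c in a_cols]
    ib = [m.columns.get_loc(c) for c in b_cols]
    contrib = np.zeros(x.shape[0])
    n_pairs = 0
    for j in ia:
        for k in ib:
            den = (x[:, j] + x[:, k]).sum()
            if den > 0:
                contrib += np.abs(x[:, j] - x[:, k]) / den
            n_pairs += 1
    contrib /= n_pairs
    total = contrib.sum()
    out = pd.DataFrame({"mean_contribution": contrib}, index=m.index)
    out["contribution_pct"] = 100 * contrib / total if total > 0 else 0.0
    out = out.sort_values("mean_contribution", ascending=False)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return out


def relate(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999,
           seed: int = 0, exhaustive: bool = False) -> tuple[float, float]:
    """Mantel-type RELATE test: Spearman rho between two distance matrices.

    Significance by permuting the sample identities of the second matrix
    (one-sided, large positive rho), with the +1 correction.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share samples in order")
    n = len(d1.ids)
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]

    def rho_for(mat: np.ndarray) -> float:
        return float(stats.spearmanr(x, mat[iu]).statistic)

    rho = rho_for(d2.data)
    if exhaustive:
        perms = [np.array(p) for p in permutations(range(n))]
        count = sum(rho_for(d2.data[np.ix_(pi, pi)]) >= rho - 1e-12
                    for pi in perms)
        return rho, count / len(perms)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        pi = rng.permutation(n)
        if rho_for(d2.data[np.ix_(pi, pi)]) >= rho - 1e-12:
            count += 1
    return rho, (1 + count) / (n_perm + 1)
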