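"""Diversity indices, rarefaction and the univariate test battery.

Shannon entropy H is reported in nats; Buzas-Gibson evenness is
E = exp(H) / S with S the observed richness.  Group comparisons use
permutation t tests with Bonferroni control, the Mann-Whitney U test, and
Kendall tau-b correlations of environmental series against rain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiversityResult",
    "shannon_evenness",
    "diversity_table",
    "rarefaction_curve",
    "per_feature_group_test",
    "mann_whitney",
    "kendall_rain_correlation",
]


@dataclass
class DiversityResult:
    sample_id: str
    S: int      # richness (count of taxa with reads)
    H: float    # Shannon entropy, nats
    E: float    # Buzas-Gibson evenness e^H / S


def shannon_evenness(profile, sample_id: str = "", base: float = math.e
                     ) -> DiversityResult:
    """Shannon entropy and Buzas-Gibson evenness of one abundance profile."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero profile")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    s = int(p.size)
    e = float(math.exp(h) / s)
    return DiversityResult(sample_id, s, h / math.log(base), e)


def diversity_table(m: pd.DataFrame) -> pd.DataFrame:
    """Per-sample S, H, E for a feature-by-sample count matrix."""
    rows = [shannon_evenness(m[c].values, str(c)) for c in m.columns]
    return pd.DataFrame({"sample_id": [r.sample_id for r in rows],
                         "S": [r.S for r in rows],
                         "H": [r.H for r in rows],
                         "E": [r.E for r in rows]}).set_index("sample_id")


def rarefaction_curve(counts, depths, reps: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean number of distinct taxa among subsamples of increasing size.

    ``counts`` is the per-taxon read-count vector of one sample; at each
    depth, reads are drawn without replacement ``reps`` times and the mean
    taxon count is reported.
    """
    c = np.asarray(counts, dtype=np.int64)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = int(c.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 or d > total for d in depths):
        raise ValueError(f"depths must be in [1, {total}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    means = []
    for d in depths:
        if d == total:
            means.append(float((c > 0).sum()))
            continue
        vals = [int((rng.multivariate_hypergeometric(c, d) > 0).sum())
                for _ in range(reps)]
        means.append(float(np.mean(vals)))
    return pd.DataFrame({"depth": depths, "mean_richness": means})


def expected_rarefaction(counts, depth: int) -> float:
    """Closed-form hypergeometric expectation of rarefied richness.

    E[S_d] = sum_i 1 - C(N - n_i, d) / C(N, d); used as the analytic
    reference for the Monte-Carlo curve.
    """
    c = np.asarray(counts, dtype=np.int64)
    n = int(c.sum())
    out = 0.0
    for ci in c[c > 0]:
        if n - ci >= depth:
            out += 1.0 - math.comb(n - ci, depth) / math.comb(n, depth)
        else:
            out += 1.0
    return out


def _welch_t(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistics for a 2-level label vector."""
    a, b = x[:, labels], x[:, ~labels]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1) / na
    vb = b.var(axis=1, ddof=1) / nb
    denom = np.sqrt(va + vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / denom
    return np.where(denom > 0, t, 0.0)


def per_feature_group_test(m: pd.DataFrame, groups, n_perm: int = 999,
                           alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Per-feature two-group permutation t test with Bonferroni control.

    For each feature row a Welch t statistic is computed; its p-value is
    the +1-corrected fraction of label permutations with |t*| >= |t|.
    A feature is flagged significant when p <= alpha / n_features.
    """
    groups = pd.Series(list(groups))
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    mask = (groups == levels[0]).values
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    x = m.values.astype(float)
    t_obs = _welch_t(x, mask)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(mask)
        exceed += np.abs(_welch_t(x, perm)) >= np.abs(t_obs) - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame({"t": t_obs, "p": p,
                         "significant": p <= alpha / x.shape[0]},
                        index=m.index)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (midrank ties) with a two-sided p-value.

    Exact p by enumeration of group assignments when n_a + n_b <= 12;
    normal approximation with tie correction otherwise.  Returns
    (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    n = na + nb
    if n <= 12:
        mu = na * nb / 2
        stat_obs = abs(u_a - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2
            if abs(u - mu) >= stat_obs - 1e-12:
                count += 1
            total += 1
        return u_a, count / total
    # asymptotic with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = na * nb / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u_a, 1.0
    z = (u_a - na * nb / 2) / math.sqrt(sigma2)
    return u_a, float(2 * stats.norm.sf(abs(z)))


def kendall_rain_correlation(env_table: pd.DataFrame, rain) -> pd.DataFrame:
    """Kendall tau-b of each environmental variable against the rain series.

    Exact p for n <= 10 with untied data, normal approximation otherwise
    (scipy's 'auto' policy).
    """
    rain = np.asarray(rain, dtype=float)
    if len(rain) != len(env_table):
        raise ValueError("environmental table and rain series lengths differ")
    if len(rain) < 3:
        raise ValueError("need at least 3 aligned observations")
    rows = {}
    for col in env_table.columns:
        res = stats.kendalltau(env_table[col].values, rain, variant="b",
                               method="auto")
        rows[col] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["tau_b", "p"])
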