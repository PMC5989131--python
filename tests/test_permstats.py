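"""PERMANOVA, PERMDISP, SIMPER and RELATE."""

import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as skd
from skbio.stats.distance import DistanceMatrix

from benthos import synthio, profiles
from benthos.permstats import (gower_center, permanova, permdisp, relate,
                               simper)


def _euclid(x):
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


class TestPermanova:
    def test_univariate_equals_classical_anova(self):
        """(0,1,2,3) in groups AA/BB: SSB=4, SSW=1, F=(4/1)/(1/2)=8 and the
        exhaustive permutation p is 1/3."""
        dm = DistanceMatrix(_euclid([0, 1, 2, 3]), list("wxyz"))
        md = pd.DataFrame({"grp": ["A", "A", "B", "B"]}, index=list("wxyz"))
        res = permanova(dm, md, ["grp"], exhaustive=True)
        assert res.loc["grp", "pseudo_F"] == pytest.approx(8.0)
        assert res.loc["grp", "p"] == pytest.approx(1 / 3)
        assert res.loc["grp", "SS"] == pytest.approx(4.0)
        assert res.loc["Residual", "SS"] == pytest.approx(1.0)

    def test_matches_skbio_one_way_F(self, rng):
        x = rng.random((12, 5))
        dm = DistanceMatrix(_euclid(x), [f"s{i}" for i in range(12)])
        grp = ["A"] * 6 + ["B"] * 6
        md = pd.DataFrame({"grp": grp}, index=dm.ids)
        mine = permanova(dm, md, ["grp"], n_perm=99, seed=0)
        ref = skd.permanova(dm, grouping=grp, permutations=99)
        assert mine.loc["grp", "pseudo_F"] == pytest.approx(
            ref["test statistic"], rel=1e-9)

    def test_ss_partition_sums_to_total(self, rng):
        md = synthio.generate_metadata(3)
        params = synthio.SimulationParams(n_reps=3, n_taxa=20,
                                          library_sizes=1000, seed=4)
        truth, *_ = synthio.generate_profiles_and_hits(md, params,
                                                       with_hits=False)
        dm = profiles.distance(truth, "braycurtis")
        res = permanova(dm, md, ["land_use", "timing", "rain_event"],
                        ["rain_event"], n_perm=49, seed=1, pool_threshold=None)
        terms = [t for t in res.index if t not in ("Total",)]
        assert res.loc[terms, "SS"].sum() == pytest.approx(
            res.loc["Total", "SS"], abs=1e-9)
        assert res.loc[terms, "df"].sum() == res.loc["Total", "df"]

    def test_mixed_model_denominators(self):
        md = synthio.generate_metadata(2)
        params = synthio.SimulationParams(n_reps=2, n_taxa=15,
                                          library_sizes=800, seed=6)
        truth, *_ = synthio.generate_profiles_and_hits(md, params,
                                                       with_hits=False)
        dm = profiles.distance(truth, "braycurtis")
        res = permanova(dm, md, ["land_use", "timing", "rain_event"],
                        ["rain_event"], n_perm=49, seed=2, pool_threshold=None)
        # fixed factors tested against their interaction with the random RE
        assert res.loc["land_use", "denominator"] == "land_use x rain_event"
        assert res.loc["timing", "denominator"] == "timing x rain_event"
        assert res.loc["rain_event", "denominator"] == "Residual"
        assert res.loc["land_use x timing", "denominator"] == \
            "land_use x timing x rain_event"

    def test_pooling_flags_weak_interactions(self):
        md = synthio.generate_metadata(3)
        params = synthio.SimulationParams(n_reps=3, n_taxa=20,
                                          library_sizes=1000, seed=9)
        truth, *_ = synthio.generate_profiles_and_hits(md, params,
                                                       with_hits=False)
        dm = profiles.distance(truth, "braycurtis")
        res = permanova(dm, md, ["land_use", "timing", "rain_event"],
                        ["rain_event"], n_perm=199, seed=3,
                        pool_threshold=0.0)  # pool everything poolable
        inter = [t for t in res.index if " x " in t]
        assert res.loc[inter, "pooled"].all()
        # pooled df land in the residual
        assert res.loc["Residual", "df"] == res.loc["Total", "df"] - 3

    def test_null_p_not_small(self):
        md = synthio.generate_metadata(2)
        ps = []
        for s in range(10):
            params = synthio.SimulationParams(n_reps=2, n_taxa=15,
                                              library_sizes=800, seed=12 + s)
            truth, *_ = synthio.generate_profiles_and_hits(md, params,
                                                           with_hits=False)
            dm = profiles.distance(truth, "braycurtis")
            res = permanova(dm, md, ["land_use"], n_perm=199, seed=s)
            ps.append(res.loc["land_use", "p"])
        assert np.median(ps) >= 0.3
        assert min(ps) > 0.01

    def test_unbalanced_design_rejected(self):
        dm = DistanceMatrix(_euclid([0, 1, 2]), list("abc"))
        md = pd.DataFrame({"grp": ["A", "A", "B"]}, index=list("abc"))
        with pytest.raises(ValueError):
            permanova(dm, md, ["grp"], n_perm=9)


class TestPermdisp:
    def test_mirror_groups_have_equal_dispersion(self):
        x = np.array([[0.0], [1.0], [10.0], [11.0]])
        dm = DistanceMatrix(_euclid(x), list("abcd"))
        res = permdisp(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res["F"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] > 0.5

    def test_univariate_matches_levene_style_computation(self, rng):
        x = rng.normal(0, 1, 10)
        x[5:] *= 3
        dm = DistanceMatrix(_euclid(x), [f"s{i}" for i in range(10)])
        grp = np.array(["a"] * 5 + ["b"] * 5)
        res = permdisp(dm, grp, n_perm=99, seed=1)
        z = np.abs(np.concatenate([x[:5] - x[:5].mean(), x[5:] - x[5:].mean()]))
        grand = z.mean()
        ssb = 5 * (z[:5].mean() - grand) ** 2 + 5 * (z[5:].mean() - grand) ** 2
        ssw = ((z[:5] - z[:5].mean()) ** 2).sum() + ((z[5:] - z[5:].mean()) ** 2).sum()
        assert res["F"] == pytest.approx((ssb / 1) / (ssw / 8))

    def test_scaled_group_detected_with_power(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            a = r.normal(0, 1, size=(10, 3))
            b = r.normal(0, 10, size=(10, 3))
            x = np.vstack([a, b])
            dm = DistanceMatrix(_euclid(x), [f"s{i}" for i in range(20)])
            res = permdisp(dm, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=s)
            hits += res["p"] <= 0.05
        assert hits >= 19  # significant in >= 95% of seeds

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(_euclid([0, 1, 2]), list("abc"))
        with pytest.raises(ValueError):
            permdisp(dm, ["a", "a", "b"], n_perm=9)


class TestSimper:
    def test_single_pair_decomposition(self):
        m = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [3.0, 2, 1]},
                         index=["t1", "t2", "t3"])
        res = simper(m, ["A", "B"])
        assert res.loc["t1", "mean_contribution"] == pytest.approx(2 / 12)
        assert res.loc["t3", "mean_contribution"] == pytest.approx(2 / 12)
        assert res.loc["t2", "mean_contribution"] == 0.0
        assert res["mean_contribution"].sum() == pytest.approx(1 / 3)

    def test_identical_groups_contribute_nothing(self):
        m = pd.DataFrame({"s1": [1.0, 2], "s2": [1.0, 2]}, index=["a", "b"])
        res = simper(m, ["A", "B"])
        assert (res["mean_contribution"] == 0).all()

    def test_contributions_sum_to_mean_between_braycurtis(self, rng):
        m = pd.DataFrame(rng.integers(0, 20, size=(8, 6)).astype(float),
                         columns=[f"s{i}" for i in range(6)])
        groups = ["A"] * 3 + ["B"] * 3
        res = simper(m, groups)
        d = profiles.distance(m, "braycurtis")
        between = [d[f"s{j}", f"s{k}"] for j in range(3) for k in range(3, 6)]
        assert res["mean_contribution"].sum() == pytest.approx(np.mean(between))
        assert res["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_empty_group_rejected(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError):
            simper(m, ["A", "A"])


class TestRelate:
    def test_monotone_transform_gives_rho_one(self, rng):
        d = _euclid(rng.random((6, 3)))
        ids = [f"s{i}" for i in range(6)]
        d1 = DistanceMatrix(d, ids)
        d2 = DistanceMatrix(np.sqrt(d), ids)
        rho, p = relate(d1, d2, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p <= 0.05

    def test_sampled_p_close_to_exhaustive(self, rng):
        d1 = DistanceMatrix(_euclid(rng.random(4)), list("abcd"))
        d2 = DistanceMatrix(_euclid(rng.random(4)), list("abcd"))
        rho_e, p_e = relate(d1, d2, exhaustive=True)
        rho_s, p_s = relate(d1, d2, n_perm=1999, seed=1)
        assert rho_s == pytest.approx(rho_e)
        assert abs(p_s - p_e) < 0.06

    def test_null_p_roughly_uniform(self):
        ps = []
        for s in range(60):
            r = np.random.default_rng(s)
            ids = [f"s{i}" for i in range(8)]
            d1 = DistanceMatrix(_euclid(r.random((8, 3))), ids)
            d2 = DistanceMatrix(_euclid(r.random((8, 3))), ids)
            ps.append(relate(d1, d2, n_perm=99, seed=s)[1])
        ps = np.array(ps)
        # super-uniformity at a couple of quantiles
        assert 0.2 < (ps <= 0.5).mean() < 0.8
        assert (ps <= 0.1).mean() <= 0.25

    def test_mismatched_samples_rejected(self):
        d1 = DistanceMatrix(np.zeros((3, 3)), list("abc"))
        d2 = DistanceMatrix(np.zeros((3, 3)), list("abd"))
        with pytest.raises(ValueError):
            relate(d1, d2)


def test_gower_centering_recovers_total_ss(rng):
    """tr(G) equals the classical total sum of squares for Euclidean
    distances on centered data."""
    x = rng.normal(0, 1, size=(10, 4))
    g = gower_center(_euclid(x))
    ss_total = ((x - x.mean(axis=0)) ** 2).sum()
    assert np.trace(g) == pytest.approx(ss_total)
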