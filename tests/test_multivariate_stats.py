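import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_ind

from penguinproc.community_matrix import AbundanceMatrix, DistanceMatrix
from penguinproc.io_formats import SampleMetadata
from penguinproc.multivariate_stats import (
    NmdsResult,
    bh_adjust,
    differential_abundance,
    group_ellipses,
    isotonic_fit,
    nmds,
    permanova,
    welch_t,
)


def dm_from_points(points):
    pts = np.asarray(points, dtype=float)
    d = squareform(pdist(pts))
    return DistanceMatrix([f"p{i}" for i in range(len(pts))], d)


class TestIsotonicFit:
    def test_monotone_identity(self):
        y = np.array([1.0, 2.0, 2.0, 5.0])
        np.testing.assert_allclose(isotonic_fit(y), y)

    def test_pool_example(self):
        np.testing.assert_allclose(isotonic_fit(np.array([3.0, 1.0, 2.0])),
                                   [2.0, 2.0, 2.0])

    def test_matches_sklearn(self):
        from sklearn.isotonic import IsotonicRegression

        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.normal(size=rng.integers(2, 30))
            ours = isotonic_fit(y)
            ref = IsotonicRegression().fit_transform(np.arange(len(y)), y)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            isotonic_fit(np.array([]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_output_non_decreasing(self, values):
        out = isotonic_fit(np.array(values))
        assert (np.diff(out) >= -1e-12).all()


def stress1_of(config, d_obs):
    """Independent stress evaluation using sklearn isotonic regression."""
    from sklearn.isotonic import IsotonicRegression

    e = pdist(np.asarray(config, dtype=float).reshape(len(d_obs_ids), -1))
    order = np.argsort(d_obs, kind="stable")
    dhat = np.empty_like(e)
    dhat[order] = IsotonicRegression().fit_transform(np.arange(len(e)), e[order])
    return np.sqrt(((e - dhat) ** 2).sum() / (e**2).sum())


d_obs_ids = None  # set inside the oracle test


class TestNmds:
    def test_collinear_points_embed_at_k1(self):
        dm = dm_from_points([[0.0], [1.0], [2.5], [4.0], [7.0]])
        res = nmds(dm, k=1, n_starts=10, seed=0)
        assert res.stress < 1e-3

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(1)
        dm = dm_from_points(rng.random((8, 3)))
        res = nmds(dm, k=2, n_starts=5, seed=1)
        assert res.stress_history
        assert (np.diff(res.stress_history) <= 1e-12).all()

    def test_four_point_oracle(self):
        # brute-force configuration search at k=1 (one coordinate fixed at 0)
        from scipy.optimize import minimize
        from sklearn.isotonic import IsotonicRegression

        d_full = np.array([
            [0.0, 1.0, 2.0, 3.5],
            [1.0, 0.0, 1.2, 2.0],
            [2.0, 1.2, 0.0, 1.1],
            [3.5, 2.0, 1.1, 0.0],
        ])
        d = squareform(d_full)
        order = np.argsort(d, kind="stable")

        def stress(free):
            x = np.concatenate([[0.0], free])[:, None]
            e = pdist(x)
            if np.any(e == 0):
                return 1.0
            dhat = np.empty_like(e)
            dhat[order] = IsotonicRegression().fit_transform(
                np.arange(len(e)), e[order])
            return np.sqrt(((e - dhat) ** 2).sum() / (e**2).sum())

        grid = np.linspace(-4, 4, 13)
        best = min(
            (stress(np.array(c)) , c)
            for c in itertools.product(grid, repeat=3)
        )
        polished = minimize(stress, np.array(best[1]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        oracle = min(best[0], polished.fun)
        res = nmds(DistanceMatrix(list("abcd"), d_full), k=1, n_starts=30, seed=2)
        assert res.stress <= oracle + 1e-3

    def test_stress_invariant_to_distance_scaling(self):
        rng = np.random.default_rng(3)
        dm = dm_from_points(rng.random((7, 3)))
        scaled = DistanceMatrix(list(dm.ids), dm.values * 3.7)
        r1 = nmds(dm, seed=4, n_starts=8)
        r2 = nmds(scaled, seed=4, n_starts=8)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-6)

    def test_scores_centred(self):
        rng = np.random.default_rng(5)
        dm = dm_from_points(rng.random((6, 2)))
        res = nmds(dm, seed=5, n_starts=5)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_too_few_samples(self):
        dm = dm_from_points([[0.0], [1.0]])
        with pytest.raises(ValueError):
            nmds(dm, k=2)

    def test_degenerate_distances_flagged(self):
        d = np.ones((4, 4)) - np.eye(4)
        res = nmds(DistanceMatrix(list("abcd"), d), k=2, seed=0)
        assert not res.converged


def _balanced_meta(n_per_group=3):
    factors = {}
    i = 0
    for sp in ("chinstrap", "gentoo"):
        for stg in ("feeding", "moulting"):
            for _ in range(n_per_group):
                factors[f"s{i}"] = (sp, stg)
                i += 1
    return SampleMetadata(factors)


class TestPermanova:
    def test_invariants_balanced(self):
        meta = _balanced_meta(3)
        rng = np.random.default_rng(0)
        dm = dm_from_points(rng.random((12, 6)))
        dm = DistanceMatrix(meta.sample_ids, dm.values)
        res = permanova(dm, meta, n_perm=99, seed=1)
        t = res.table
        n = 12
        assert t.loc["Total", "df"] == n - 1
        assert t["df"].drop("Total").sum() == n - 1
        model_terms = ["species", "stage", "species:stage"]
        ss_sum = t.loc[model_terms, "SS"].sum() + t.loc["Residual", "SS"]
        assert ss_sum == pytest.approx(t.loc["Total", "SS"], abs=1e-9)
        for term in model_terms:
            assert 1 / 100 <= t.loc[term, "p"] <= 1.0

    def test_f_invariant_under_distance_scaling(self):
        meta = _balanced_meta(3)
        rng = np.random.default_rng(2)
        base = dm_from_points(rng.random((12, 6)))
        dm1 = DistanceMatrix(meta.sample_ids, base.values)
        dm2 = DistanceMatrix(meta.sample_ids, base.values * 2.5)
        f1 = permanova(dm1, meta, n_perm=9, seed=0).table["pseudo_F"]
        f2 = permanova(dm2, meta, n_perm=9, seed=0).table["pseudo_F"]
        np.testing.assert_allclose(f1.dropna(), f2.dropna(), rtol=1e-10)

    def test_single_level_factor_rejected(self):
        factors = {f"s{i}": ("chinstrap", "feeding" if i % 2 else "moulting")
                   for i in range(6)}
        meta = SampleMetadata(factors)
        rng = np.random.default_rng(3)
        d = dm_from_points(rng.random((6, 3)))
        dm = DistanceMatrix(list(factors), d.values)
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, meta, terms=("species",), n_perm=9)

    def test_bad_n_perm(self):
        meta = _balanced_meta(3)
        rng = np.random.default_rng(4)
        dm = DistanceMatrix(meta.sample_ids, dm_from_points(rng.random((12, 2))).values)
        with pytest.raises(ValueError):
            permanova(dm, meta, n_perm=0)

    def test_matches_exact_enumeration_single_factor(self):
        # n = 6, one factor, 3 vs 3: exact p over all 6! relabelings
        import pandas as pd

        rng = np.random.default_rng(5)
        pts = rng.random((6, 3))
        pts[:3] += 0.8  # real effect
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(ids, d)
        factors = pd.DataFrame({"group": ["x"] * 3 + ["y"] * 3}, index=ids)

        labels = np.array([0, 0, 0, 1, 1, 1])
        a = -0.5 * d**2
        j = np.eye(6) - np.full((6, 6), 1 / 6)
        g = j @ a @ j

        def f_stat(lab):
            x = np.column_stack([np.ones(6), lab])
            h = x @ np.linalg.pinv(x)
            h0 = np.full((6, 6), 1 / 6)
            ss_term = ((h - h0) * g).sum()
            ss_res = ((np.eye(6) - h) * g).sum()
            return (ss_term / 1) / (ss_res / 4)

        f_obs = f_stat(labels)
        perms = [f_stat(labels[list(p)]) for p in itertools.permutations(range(6))]
        exact_p = np.mean([f >= f_obs - 1e-12 for f in perms])

        res = permanova(dm, factors, terms=("group",), n_perm=999, seed=0)
        assert abs(res.table.loc["group", "p"] - exact_p) < 0.02


class TestWelchT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        res = welch_t(x, x.copy())
        assert res.t == 0.0
        assert res.p == 1.0

    def test_equal_variance_equal_n_df(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10
        res = welch_t(x, y)
        assert res.df == pytest.approx(len(x) + len(y) - 2)

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 20))
            y = rng.normal(0.3, 2, rng.integers(3, 20))
            ours = welch_t(x, y)
            ref = ttest_ind(x, y, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_df_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n1, n2 = rng.integers(2, 15, 2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            res = welch_t(x, y)
            assert min(n1, n2) - 1 <= res.df <= n1 + n2 - 2 + 1e-9

    def test_zero_variance_both_rejected(self):
        with pytest.raises(ValueError):
            welch_t(np.array([1.0, 1.0]), np.array([2.0, 2.0]))

    def test_too_small(self):
        with pytest.raises(ValueError):
            welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestBhAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(25)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestDifferentialAbundance:
    def _rel(self, values, meta):
        return AbundanceMatrix(meta.sample_ids,
                               [f"T{j}" for j in range(values.shape[1])], values)

    def test_identical_proportions_p_one(self):
        meta = SampleMetadata({
            **{f"f{i}": ("gentoo", "feeding") for i in range(3)},
            **{f"m{i}": ("gentoo", "moulting") for i in range(3)},
        })
        vals = np.tile([0.6, 0.4], (6, 1))
        res = differential_abundance(self._rel(vals, meta), meta, "gentoo",
                                     min_prevalence=0.0)
        assert (res["p"] == 1.0).all()

    def test_power_simulation(self):
        # shift delta=0.3, sigma=0.05, n=6/6 -> raw p < 0.01 in >= 95% of 200 sims
        rng = np.random.default_rng(10)
        meta = SampleMetadata({
            **{f"f{i}": ("gentoo", "feeding") for i in range(6)},
            **{f"m{i}": ("gentoo", "moulting") for i in range(6)},
        })
        hits = 0
        for _ in range(200):
            feeding = rng.normal(0.5, 0.05, 6)
            moulting = rng.normal(0.2, 0.05, 6)
            col = np.clip(np.concatenate([feeding, moulting]), 1e-6, 1)
            vals = np.column_stack([col, 1 - col])
            res = differential_abundance(self._rel(vals, meta), meta, "gentoo",
                                         min_prevalence=0.0)
            hits += res.loc[res["taxon"] == "T0", "p"].iloc[0] < 0.01
        assert hits >= 190

    def test_bh_monotone(self):
        rng = np.random.default_rng(11)
        meta = SampleMetadata({
            **{f"f{i}": ("chinstrap", "feeding") for i in range(4)},
            **{f"m{i}": ("chinstrap", "moulting") for i in range(4)},
        })
        vals = rng.dirichlet(np.ones(5), size=8)
        res = differential_abundance(self._rel(vals, meta), meta, "chinstrap",
                                     min_prevalence=0.0)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestGroupEllipses:
    def _result(self, pts, ids):
        return NmdsResult(ids, np.asarray(pts, dtype=float), 0.05, True, 1)

    def test_identical_points_zero_sd(self):
        meta = SampleMetadata({f"s{i}": ("gentoo", "feeding") for i in range(4)})
        res = self._result([[1.0, 2.0]] * 4, meta.sample_ids)
        (ell,) = group_ellipses(res, meta)
        np.testing.assert_allclose(ell.sds, 0.0, atol=1e-12)

    def test_centroid_is_mean(self):
        meta = SampleMetadata({f"s{i}": ("gentoo", "feeding") for i in range(5)})
        rng = np.random.default_rng(12)
        pts = rng.random((5, 2))
        (ell,) = group_ellipses(self._result(pts, meta.sample_ids), meta)
        np.testing.assert_allclose(ell.centroid, pts.mean(axis=0))

    def test_isotropic_cloud_sds(self):
        meta = SampleMetadata({f"s{i}": ("gentoo", "feeding") for i in range(1000)})
        rng = np.random.default_rng(13)
        sigma = 0.8
        pts = rng.normal(0, sigma, (1000, 2))
        (ell,) = group_ellipses(self._result(pts, meta.sample_ids), meta)
        assert np.abs(ell.sds - sigma).max() < 0.15 * sigma

    def test_small_group_skipped(self):
        meta = SampleMetadata({
            "a": ("gentoo", "feeding"), "b": ("gentoo", "feeding"),
            "c": ("gentoo", "feeding"),
            "d": ("gentoo", "moulting"), "e": ("gentoo", "moulting"),
        })
        res = self._result(np.random.default_rng(14).random((5, 2)),
                           meta.sample_ids)
        ellipses = group_ellipses(res, meta)
        assert [e.group for e in ellipses] == ["gentoo_feeding"]
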