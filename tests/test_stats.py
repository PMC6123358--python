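import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from culturomics import (
    OtuTable,
    euclidean_distances,
    holm_bonferroni,
    kruskal_wallis,
    pcoa,
    percentile_cultivability_correlation,
    permanova_two_way,
    wilcoxon_rank_sum_exact,
    wilcoxon_signed_rank_exact,
)
from culturomics.stats import apply_significance


class TestEuclideanDistances:
    def test_matches_scipy(self, rng):
        from scipy.spatial.distance import pdist, squareform

        data = rng.random((6, 10))
        data /= data.sum(axis=1, keepdims=True)
        table = OtuTable(
            pd.DataFrame(data, index=[f"s{i}" for i in range(6)],
                         columns=[f"o{j}" for j in range(10)]),
            relative=True,
        )
        D = euclidean_distances(table)
        assert np.allclose(D.data, squareform(pdist(data)))
        assert list(D.ids) == table.sample_ids

    def test_warns_on_unequal_totals(self):
        table = OtuTable(
            pd.DataFrame({"a": [5, 1], "b": [5, 1]}, index=["s1", "s2"])
        )
        with pytest.warns(UserWarning, match="totals"):
            euclidean_distances(table)


class TestPcoa:
    def _random_distances(self, rng, n=8):
        points = rng.random((n, 4))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(
            squareform(pdist(points)), ids=[f"s{i}" for i in range(n)]
        ), points

    def test_matches_skbio_oracle(self, rng):
        import skbio.stats.ordination as skord

        D, _ = self._random_distances(rng)
        ours = pcoa(D)
        theirs = skord.pcoa(D, method="eigh")
        k = ours.coordinates.shape[1]
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )
        assert np.allclose(
            ours.proportion_explained[:k],
            theirs.proportion_explained.to_numpy()[:k],
            atol=1e-10,
        )

    def test_euclidean_embedding_preserves_distances(self, rng):
        from scipy.spatial.distance import pdist

        D, _ = self._random_distances(rng)
        ours = pcoa(D)
        recon = pdist(ours.coordinates.to_numpy())
        from scipy.spatial.distance import squareform

        assert np.allclose(squareform(recon), D.data, atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        D, _ = self._random_distances(rng)
        a = pcoa(D).coordinates
        b = pcoa(D).coordinates
        assert a.equals(b)
        # largest |loading| on every axis is positive
        arr = a.to_numpy()
        picks = np.abs(arr).argmax(axis=0)
        assert (arr[picks, np.arange(arr.shape[1])] > 0).all()


class TestPermanova:
    def _dist(self, rng, n):
        from scipy.spatial.distance import pdist, squareform

        pts = rng.random((n, 3))
        return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])

    def test_one_way_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as sk_permanova

        n = 12
        D = self._dist(rng, n)
        grouping = ["g1"] * 6 + ["g2"] * 6
        ours = permanova_two_way(
            D, grouping, ["x"] * n, B=999, seed=0, names=("group", "const")
        )
        theirs = sk_permanova(D, grouping, permutations=999)
        f = ours.factor("group")
        assert f.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert f.p_value == pytest.approx(theirs["p-value"], abs=0.05)
        const = ours.factor("const")
        assert const.df == 0 and const.p_value == 1.0

    def test_sums_of_squares_partition(self, rng):
        n = 16
        D = self._dist(rng, n)
        a = (["a1"] * 8 + ["a2"] * 8)
        b = (["b1", "b2"] * 8)
        res = permanova_two_way(D, a, b, B=99, seed=1)
        ss = [f.sum_of_squares for f in res.factors]
        assert sum(ss) + res.residual_ss == pytest.approx(res.total_ss)
        assert res.residual_df == n - 1 - sum(f.df for f in res.factors)

    def test_balanced_design_order_invariant(self, rng):
        n = 16
        D = self._dist(rng, n)
        a = (["a1"] * 8 + ["a2"] * 8)
        b = (["b1", "b2"] * 8)
        r1 = permanova_two_way(D, a, b, B=9, seed=0, names=("A", "B"))
        r2 = permanova_two_way(D, b, a, B=9, seed=0, names=("B", "A"))
        assert r1.factor("A").sum_of_squares == pytest.approx(
            r2.factor("A").sum_of_squares
        )
        assert r1.factor("B").sum_of_squares == pytest.approx(
            r2.factor("B").sum_of_squares
        )

    def test_aliased_factors_rejected(self, rng):
        n = 8
        D = self._dist(rng, n)
        a = ["a1"] * 4 + ["a2"] * 4
        with pytest.raises(ValueError, match="aliased"):
            permanova_two_way(D, a, list(a), B=9)

    def test_signal_detected(self, rng):
        """Two clearly separated clusters give a small P for the cluster factor."""
        from scipy.spatial.distance import pdist, squareform

        pts = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(5, 0.1, (8, 3))])
        D = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(16)])
        a = ["c1"] * 8 + ["c2"] * 8
        b = ["b1", "b2"] * 8
        res = permanova_two_way(D, a, b, B=999, seed=0, names=("cluster", "rep"))
        assert res.factor("cluster").p_value < 0.01
        assert res.factor("cluster").variance_explained > 0.9


class TestSignedRank:
    def test_six_pairs_same_sign(self):
        """n=6 pairs all in one direction: exact two-sided P = 2/64."""
        x = [10, 12, 9, 14, 11, 13]
        y = [8, 10, 8, 12, 10, 11]
        assert wilcoxon_signed_rank_exact(x, y) == pytest.approx(0.03125)

    def test_matches_scipy_exact_no_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 15))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ours = wilcoxon_signed_rank_exact(x, y)
            theirs = sps.wilcoxon(x, y, mode="exact").pvalue
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_ties_midranks(self):
        # differences: +1, +1, -1, +2 -> doubled midranks handle the ties
        p = wilcoxon_signed_rank_exact([2, 2, 1, 4], [1, 1, 2, 2])
        assert 0 < p <= 1

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])

    def test_large_n_uses_normal_tail(self, rng):
        x = rng.normal(0.5, 1, 40)
        y = rng.normal(0.0, 1, 40)
        p = wilcoxon_signed_rank_exact(x, y)
        theirs = sps.wilcoxon(x, y, mode="approx", correction=False).pvalue
        assert p == pytest.approx(theirs, rel=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda v: round(v, 2)),
            min_size=2, max_size=12,
        ),
        st.integers(0, 2**31 - 1),
    )
    def test_symmetry_property(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = [x + d for x, d in zip(xs, rng.normal(0, 5, len(xs)).round(2))]
        if all(x == y for x, y in zip(xs, ys)):
            return
        # swapping the roles of x and y leaves the two-sided P unchanged
        assert wilcoxon_signed_rank_exact(xs, ys) == pytest.approx(
            wilcoxon_signed_rank_exact(ys, xs)
        )


class TestRankSum:
    def test_matches_scipy_exact_no_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            ours = wilcoxon_rank_sum_exact(x, y)
            theirs = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue
            assert ours == pytest.approx(theirs, rel=1e-9)

    def test_extreme_separation(self):
        # 6 vs 6 fully separated: exact two-sided P = 2 / C(12, 6)
        p = wilcoxon_rank_sum_exact([1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14, 15])
        assert p == pytest.approx(2 / 924)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_exact([], [1.0])

    def test_large_samples_asymptotic(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.8, 1, 30)
        p = wilcoxon_rank_sum_exact(x, y)
        theirs = sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic", use_continuity=False).pvalue
        assert p == pytest.approx(theirs, rel=1e-9)


class TestKruskal:
    def test_matches_scipy(self, rng):
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        h, p = kruskal_wallis(groups)
        h2, p2 = sps.kruskal(*groups)
        assert h == pytest.approx(h2) and p == pytest.approx(p2)

    def test_identical_values_degenerate(self):
        assert kruskal_wallis([[1.0, 1.0], [1.0], [1.0, 1.0]]) == (0.0, 1.0)

    def test_bad_input(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestHolm:
    def test_hand_example(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        # sorted: 0.01*3=0.03, 0.03*2=0.06, 0.04*2 -> monotone max 0.06
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_empty_and_bounds(self):
        assert holm_bonferroni([]).size == 0
        assert (holm_bonferroni([1.0, 1.0]) <= 1.0).all()
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, float("nan")])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_adjusted_never_smaller(self, ps):
        adj = holm_bonferroni(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestPercentileCorrelation:
    def _counts(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 1000, n)
        return pd.Series(counts, index=[f"o{i}" for i in range(n)])

    def test_abundance_biased_subset_positive_r(self):
        counts = self._counts()
        top = counts.sort_values(ascending=False).index[:30]
        out = percentile_cultivability_correlation(
            counts, {"cultured": list(top)}, n_bins=20
        )
        cell = out["cultured"]
        assert cell["r"] > 0.3
        assert cell["p_raw"] < 0.05
        assert cell["n_ignored"] == 0

    def test_uniform_subset_weak_r(self):
        counts = self._counts()
        every_fourth = list(counts.index[::4])
        out = percentile_cultivability_correlation(
            counts, {"cultured": every_fourth}, n_bins=20
        )
        assert abs(out["cultured"]["r"]) < 0.3

    def test_undetected_members_warn_and_count(self):
        counts = self._counts(n=40)
        with pytest.warns(UserWarning, match="ignored"):
            out = percentile_cultivability_correlation(
                counts, {"s": ["o0", "o1", "ghost"]}, n_bins=10
            )
        assert out["s"]["n_ignored"] == 1

    def test_too_many_bins_rejected(self):
        counts = self._counts(n=10)
        with pytest.raises(ValueError, match="n_bins"):
            percentile_cultivability_correlation(counts, {"s": ["o0"]}, n_bins=11)

    def test_constant_y_degenerate(self):
        counts = self._counts(n=40)
        out = percentile_cultivability_correlation(counts, {"s": []}, n_bins=10)
        assert np.isnan(out["s"]["r"]) and out["s"]["p_raw"] == 1.0

    def test_bins_partition_detected_otus(self):
        counts = self._counts(n=47)
        out = percentile_cultivability_correlation(
            counts, {"all": list(counts.index)}, n_bins=10
        )
        # every detected OTU lands in exactly one bin
        assert out["all"]["n_bins"] == 10

    def test_apply_significance(self):
        cells = [
            {"r": 0.9, "p_raw": 0.001},
            {"r": 0.9, "p_raw": 0.9},
            {"r": 0.1, "p_raw": 0.001},
            {"r": float("nan"), "p_raw": 1.0},
        ]
        apply_significance(cells, r_threshold=0.3, alpha=0.05)
        assert [c["significant"] for c in cells] == [True, False, False, False]
        assert cells[0]["p_adjusted"] == pytest.approx(0.004)
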