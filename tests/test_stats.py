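"""Nonparametric battery: enumeration/brute-force oracles and null behaviour."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp
from scipy import stats as sps

import macrowear as mw
from macrowear.stats import (DegenerateDataError, DistanceMatrix, _pseudo_f,
                             bh_adjust)


class TestArcsine:
    def test_endpoints_and_quarter(self):
        assert mw.arcsine_transform(0.0) == 0.0
        assert mw.arcsine_transform(1.0) == pytest.approx(math.pi / 2)
        assert mw.arcsine_transform(0.25) == pytest.approx(math.pi / 6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            mw.arcsine_transform(1.2)


class TestMannWhitney:
    def test_exact_small_example(self):
        res = mw.mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        assert mw.mann_whitney([1, 2, 3], [1, 2, 3]).pvalue == 1.0

    def test_fully_separated_attains_enumeration_minimum(self):
        x, y = list(range(1, 11)), list(range(11, 21))
        res = mw.mann_whitney(x, y)
        # smallest attainable two-tailed p for n=m=10: 2 / C(20,10)
        assert res.pvalue == pytest.approx(2 / math.comb(20, 10))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(0.4, 1.2, size=9)
        ours = mw.mann_whitney(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_asymptotic_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, size=40).astype(float)
        y = rng.integers(1, 7, size=35).astype(float)
        ours = mw.mann_whitney(x, y, mode="asymptotic")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mw.mann_whitney([], [1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st_hyp.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=7)
        p1 = mw.mann_whitney(x, y).pvalue
        p2 = mw.mann_whitney(np.exp(x), np.exp(y)).pvalue
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestLevene:
    def test_plain_brown_forsythe_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, s, size=n) for s, n in [(1, 12), (2, 9), (1.5, 15)]]
        ours = mw.levene_brown_forsythe(groups, zero_removal=False, correction=False)
        ref = sps.levene(*groups, center="median")
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_combined_variant_matches_hand_computation(self):
        g1, g2 = [1, 2, 3, 4, 5], [10, 20, 30, 40, 50]
        # by hand: |x - med| = [2,1,0,1,2] and [20,10,0,10,20]; remove one zero
        # per odd group -> [2,1,1,2], [20,10,10,20]; O'Brien factor sqrt(4/3)
        d1 = np.array([2, 1, 1, 2]) * math.sqrt(4 / 3)
        d2 = np.array([20, 10, 10, 20]) * math.sqrt(4 / 3)
        grand = np.concatenate([d1, d2]).mean()
        ssb = 4 * (d1.mean() - grand) ** 2 + 4 * (d2.mean() - grand) ** 2
        ssw = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 6)
        ours = mw.levene_brown_forsythe([g1, g2])
        assert ours.statistic == pytest.approx(f_hand, rel=1e-12)

    def test_degenerate_zero_spread(self):
        res = mw.levene_brown_forsythe([[5, 5, 5, 5], [2, 2, 2, 2]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mw.levene_brown_forsythe([[1.0], [1, 2, 3]])

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.normal(size=12) for _ in range(3)]
            if mw.levene_brown_forsythe(groups).pvalue < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.08


class TestKruskalWallis:
    def test_hand_computed_h(self):
        res = mw.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        groups = [rng.integers(0, 5, size=n).astype(float) for n in (10, 14, 9)]
        ours = mw.kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_all_identical_gives_p_one(self):
        res = mw.kruskal_wallis([[3, 3, 3], [3, 3], [3, 3, 3]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_null_p_uniform(self):
        """Random splits of one pooled sample give uniform p-values."""
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(1000):
            pooled = rng.normal(size=30)
            rng.shuffle(pooled)
            pvals.append(mw.kruskal_wallis([pooled[:10], pooled[10:20], pooled[20:]]).pvalue)
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st_hyp.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=6) for _ in range(3)]
        h1 = mw.kruskal_wallis(groups).statistic
        h2 = mw.kruskal_wallis([np.tanh(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)


class TestBHAdjust:
    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_mixed_example(self):
        # hand step-up: sorted [0.01, 0.04, 0.30] -> [0.03, 0.06, 0.30]
        assert bh_adjust([0.04, 0.30, 0.01]) == pytest.approx([0.06, 0.30, 0.03])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st_hyp.lists(st_hyp.floats(1e-12, 1.0), min_size=1, max_size=20))
    def test_properties(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()
        # monotone: ordering of p-values is preserved
        order = np.argsort(pvals)
        assert (np.diff(adj[order]) >= -1e-15).all()
        # a second pass can only move adjusted p-values up, never down
        assert (bh_adjust(adj) >= adj - 1e-15).all()


class TestDunn:
    def test_identical_groups_all_p_one(self):
        table = mw.dunn_posthoc([[1, 2, 3]] * 3)
        assert (table["p_adjusted"] == 1.0).all()

    def test_symmetric_separation_equal_p(self):
        table = mw.dunn_posthoc([[1, 2], [10, 11], [100, 101]])
        # ranks are equally spaced: the two adjacent contrasts are symmetric
        z = table.set_index(["group1", "group2"])["z"].abs()
        assert z.loc[("0", "1")] == pytest.approx(z.loc[("1", "2")])

    def test_matches_rank_arithmetic(self):
        groups = [[1, 2, 5], [3, 7, 8], [4, 6, 9]]
        table = mw.dunn_posthoc(groups, labels=["a", "b", "c"])
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        rbar = [ranks[i * 3:(i + 1) * 3].mean() for i in range(3)]
        n = 9
        se = math.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        z_ab = (rbar[0] - rbar[1]) / se
        row = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        assert row.z == pytest.approx(z_ab, rel=1e-12)


class TestDistanceMatrix:
    def test_pythagorean(self):
        dm = mw.euclidean_distance_matrix([[0, 0], [3, 4]])
        assert dm.data[0, 1] == pytest.approx(5.0)

    def test_duplicate_row_zero_distance(self):
        dm = mw.euclidean_distance_matrix([[1, 2], [1, 2], [3, 3]])
        assert dm.data[0, 1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 4))
        dm = mw.euclidean_distance_matrix(x)
        for i in range(10):
            for j in range(10):
                assert dm.data[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-12)

    def test_incomplete_rows_dropped(self):
        x = np.array([[1.0, 2], [np.nan, 1], [0, 0]])
        dm = mw.euclidean_distance_matrix(x, ids=["a", "b", "c"])
        assert dm.ids == ["a", "c"]

    def test_too_few_complete_rows(self):
        with pytest.raises(ValueError):
            mw.euclidean_distance_matrix([[np.nan, 1], [np.nan, 2], [1, 2]])


def _brute_force_pseudo_f(d, labels):
    """Independent first-principles PERMANOVA pseudo-F (double loops)."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        ss_w += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    k = len(groups)
    return (ss_a / (k - 1)) / (ss_w / (n - k))


class TestPermanova:
    def test_pseudo_f_matches_brute_force_n6(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(6, 3))
        dm = mw.euclidean_distance_matrix(x)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = mw.permanova(dm, labels, seed=0)
        assert res.statistic == pytest.approx(_brute_force_pseudo_f(dm.data, labels), rel=1e-12)

    def test_exact_enumeration_two_clouds(self):
        rng = np.random.default_rng(15)
        x = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        dm = mw.euclidean_distance_matrix(x)
        labels = ["a"] * 5 + ["b"] * 5
        res = mw.permanova(dm, labels, seed=0)
        # full enumeration: C(10,5) = 252 splits; only the true split and its
        # mirror are as extreme
        assert res.method == "permanova (exact enumeration)"
        assert res.n_perm == 252
        assert res.pvalue == pytest.approx(2 / 252)

    def test_permutation_p_matches_enumeration(self):
        """Sampled permutation p agrees with exact enumeration on n=10."""
        rng = np.random.default_rng(16)
        x = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(1.0, 1, (5, 2))])
        dm = mw.euclidean_distance_matrix(x)
        labels = ["a"] * 5 + ["b"] * 5
        exact = mw.permanova(dm, labels, seed=0)  # auto-enumerates
        f_obs = exact.statistic
        hits = 0
        for combo in itertools.combinations(range(10), 5):
            lab = np.array(["b"] * 10)
            lab[list(combo)] = "a"
            if _brute_force_pseudo_f(dm.data, lab) >= f_obs - 1e-12:
                hits += 1
        assert exact.pvalue == pytest.approx(hits / 252)

    def test_one_dimensional_limit_equals_anova_f(self):
        rng = np.random.default_rng(17)
        g = [rng.normal(m, 1, size=8) for m in (0.0, 0.5, 1.0)]
        dm = mw.euclidean_distance_matrix(np.concatenate(g)[:, None])
        labels = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = mw.permanova(dm, labels, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(sps.f_oneway(*g).statistic, rel=1e-9)

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova
        rng = np.random.default_rng(18)
        x = rng.normal(size=(15, 3))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        dm = mw.euclidean_distance_matrix(x)
        ours = mw.permanova(dm, labels, seed=3)
        ref = sk_permanova(SkDM(dm.data), labels, permutations=99)
        assert ours.statistic == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(30, 3))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        dm = mw.euclidean_distance_matrix(x)
        p1 = mw.permanova(dm, labels, n_perm=199, seed=7).pvalue
        p2 = mw.permanova(dm, labels, n_perm=199, seed=7).pvalue
        assert p1 == p2

    def test_constant_matrix_degenerate(self):
        dm = DistanceMatrix(np.zeros((6, 6)), ids=list(range(6)))
        with pytest.raises(DegenerateDataError):
            mw.permanova(dm, ["a"] * 3 + ["b"] * 3, seed=0)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(20)
        pvals = []
        for _ in range(300):
            x = rng.normal(size=(18, 2))
            dm = mw.euclidean_distance_matrix(x)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
            pvals.append(mw.permanova(dm, labels, n_perm=99,
                                      seed=int(rng.integers(2 ** 31 - 1))).pvalue)
        assert sps.kstest(pvals, "uniform").statistic < 0.08


class TestBetadisper:
    def test_euclidean_case_equals_distance_to_mean(self):
        rng = np.random.default_rng(25)
        pts = rng.normal(size=(12, 2))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        disp = mw.betadisper(mw.euclidean_distance_matrix(pts), labels)
        manual = np.array([np.linalg.norm(p - pts[labels == l].mean(axis=0))
                           for p, l in zip(pts, labels)])
        assert disp.distances == pytest.approx(manual, abs=1e-10)

    def test_identical_points_zero_dispersion(self):
        x = np.ones((8, 3))
        dm = DistanceMatrix(np.zeros((8, 8)), ids=list(range(8)))
        disp = mw.betadisper(dm, ["a"] * 4 + ["b"] * 4)
        assert np.allclose(disp.distances, 0.0)

    def test_non_euclidean_matrix_real_nonnegative(self):
        # a valid metric that is not Euclidean-embeddable (negative PCoA
        # eigenvalue): unit-distance graph metric on K4 minus an edge
        d = np.array([
            [0, 1, 1, 1, 1, 2, 2, 2],
            [1, 0, 1, 1, 2, 1, 2, 2],
            [1, 1, 0, 1, 2, 2, 1, 2],
            [1, 1, 1, 0, 2, 2, 2, 1],
            [1, 2, 2, 2, 0, 3, 3, 3],
            [2, 1, 2, 2, 3, 0, 3, 3],
            [2, 2, 1, 2, 3, 3, 0, 3],
            [2, 2, 2, 1, 3, 3, 3, 0.0]])
        dm = DistanceMatrix(d, ids=list(range(8)))
        disp = mw.betadisper(dm, ["a"] * 4 + ["b"] * 4)
        assert disp.eigenvalues.min() < -1e-9  # the fixture really is non-Euclidean
        assert np.isfinite(disp.distances).all()
        assert (disp.distances >= 0).all()

    def test_matches_vegan_reference(self):
        """Cross-check distances-to-centroid against vegan::betadisper."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(26)
        pts = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        dm = mw.euclidean_distance_matrix(pts)
        disp = mw.betadisper(dm, labels)
        csv = "\n".join(",".join(f"{v:.17g}" for v in row) for row in dm.data)
        script = f"""
        suppressMessages(library(vegan))
        d <- as.dist(matrix(c({','.join(f'{v:.17g}' for v in dm.data.ravel())}), nrow=10))
        g <- factor(c(rep('a',5), rep('b',5)))
        b <- betadisper(d, g, type='centroid')
        cat(sprintf('%.15g\\n', b$distances))
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(s) for s in out.stdout.split()])
        assert disp.distances == pytest.approx(ref, abs=1e-8)


class TestDispersionTests:
    def test_equal_dispersion_rarely_rejects(self):
        rng = np.random.default_rng(30)
        hits = 0
        for _ in range(100):
            pts = rng.normal(size=(24, 2))
            labels = np.array(["a"] * 12 + ["b"] * 12)
            disp = mw.betadisper(mw.euclidean_distance_matrix(pts), labels)
            res = mw.permutest_dispersion(disp, n_perm=99, seed=int(rng.integers(2 ** 31 - 1)))
            hits += res.pvalue <= 0.05
        assert hits <= 10

    def test_scaled_cloud_detected(self):
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(100):
            a = rng.normal(size=(20, 2))
            b = rng.normal(size=(20, 2)) * 5.0
            pts = np.vstack([a, b])
            labels = np.array(["a"] * 20 + ["b"] * 20)
            disp = mw.betadisper(mw.euclidean_distance_matrix(pts), labels)
            res = mw.permutest_dispersion(disp, n_perm=99, seed=int(rng.integers(2 ** 31 - 1)))
            hits += res.pvalue <= 0.05
        assert hits >= 90

    def test_tukey_pairs_cover_all_groups(self):
        rng = np.random.default_rng(32)
        pts = rng.normal(size=(18, 2))
        labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        disp = mw.betadisper(mw.euclidean_distance_matrix(pts), labels)
        table = mw.tukey_hsd_dispersion(disp)
        assert len(table) == 3
        assert ((table["ci_low"] <= table["diff"]) & (table["diff"] <= table["ci_high"])).all()


class TestPairwisePermanova:
    def test_distant_group_flagged_only(self):
        rng = np.random.default_rng(33)
        a = rng.normal(0, 0.5, size=(8, 2))
        b = rng.normal(0, 0.5, size=(8, 2))
        c = rng.normal(20, 0.5, size=(8, 2))
        dm = mw.euclidean_distance_matrix(np.vstack([a, b, c]))
        labels = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        table = mw.pairwise_permanova(dm, labels, n_perm=199, seed=1)
        tbl = table.set_index(["group1", "group2"])
        assert tbl.loc[("a", "c"), "p_adjusted"] < 0.05
        assert tbl.loc[("b", "c"), "p_adjusted"] < 0.05
        assert tbl.loc[("a", "b"), "p_adjusted"] > 0.1

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(34)
        dm = mw.euclidean_distance_matrix(rng.normal(size=(18, 2)))
        labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        table = mw.pairwise_permanova(dm, labels, n_perm=99, seed=2)
        assert (table["p_adjusted"] >= table["pvalue"] - 1e-15).all()

    def test_needs_three_groups(self):
        rng = np.random.default_rng(35)
        dm = mw.euclidean_distance_matrix(rng.normal(size=(8, 2)))
        with pytest.raises(ValueError):
            mw.pairwise_permanova(dm, ["a"] * 4 + ["b"] * 4)
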