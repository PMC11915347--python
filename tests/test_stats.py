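"""Edge-level statistics: tests, robust fits, permutations, FDR, thresholds."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import rankdata

import gmconn as gc
from gmconn.stats import RobustFitResult

from conftest import mc_from_table


def wilcoxon_oracle(a, b):
    """Smaller-rank-sum W from first principles (zeros dropped, ties mid-ranked)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    w_neg = ranks[d < 0].sum()
    return min(w_pos, w_neg)


def bh_oracle(p):
    """Step-up BH adjustment written directly from the definition."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


class TestShapiro:
    def test_gaussian_sample_rarely_rejected(self):
        rng = np.random.default_rng(0)
        passes = sum(
            gc.shapiro_normality(rng.normal(size=800))[1] > 0.05 for _ in range(20)
        )
        assert passes >= 18

    def test_lognormal_rejected(self):
        rng = np.random.default_rng(1)
        _, p = gc.shapiro_normality(np.exp(rng.normal(size=500)))
        assert p < 0.01

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            gc.shapiro_normality([1.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            gc.shapiro_normality(np.ones(20))


class TestPairedWilcoxon:
    def test_equal_vectors_degenerate(self):
        v = np.arange(10.0)
        with pytest.raises(ValueError, match="zero"):
            gc.paired_wilcoxon(v, v)

    def test_all_positive_differences_give_w_zero(self):
        a = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        b = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        res = gc.paired_wilcoxon(a, b)
        assert res.statistic == 0.0
        assert res.direction == 1

    def test_swap_flips_direction_keeps_p(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.3, 1, 40)
        b = rng.normal(0.0, 1, 40)
        fwd = gc.paired_wilcoxon(a, b)
        rev = gc.paired_wilcoxon(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.direction == -rev.direction

    def test_matches_rank_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(5, 11)
            a = rng.normal(size=n)
            b = a + rng.normal(size=n)
            assert gc.paired_wilcoxon(a, b).statistic == wilcoxon_oracle(a, b)


class TestHuberFit:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        fit = gc.huber_fit(x, 3.0 * x + 1.0)
        assert fit.slope == pytest.approx(3.0, abs=1e-6)
        assert fit.intercept == pytest.approx(1.0, abs=1e-6)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gc.huber_fit(np.ones(20), np.arange(20.0))

    def test_robust_to_gross_outliers_beats_ols(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        y = 3.0 * x + 1.0 + 0.1 * rng.normal(size=300)
        y[::10] += 50.0
        huber = gc.huber_fit(x, y)
        ols = np.polyfit(x, y, 1)[0]
        assert abs(huber.slope - 3.0) < abs(ols - 3.0)
        assert abs(huber.slope - 3.0) < 0.1

    def test_matches_statsmodels_rlm(self):
        """statsmodels RLM with Huber's T is the independent reference fit."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.standard_t(3, size=500)
        mine = gc.huber_fit(x, y)
        ref = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT(t=1.345)).fit()
        assert mine.slope == pytest.approx(ref.params[1], rel=1e-4, abs=1e-6)
        assert mine.intercept == pytest.approx(ref.params[0], rel=1e-4, abs=1e-6)
        assert mine.slope_se == pytest.approx(ref.bse[1], rel=1e-2)


class TestPermuteSlope:
    def test_perfect_relationship_minimal_p(self):
        x = np.linspace(-1, 1, 100)
        res = gc.permute_slope_p(x, 2.0 * x, n_perm=1000, seed=0)
        assert res.permutation_p == pytest.approx(1.0 / 1001.0)

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 120))
        a = gc.permute_slope_p(x, y, n_perm=100, seed=42)
        b = gc.permute_slope_p(x, y, n_perm=100, seed=42)
        assert a.permutation_p == b.permutation_p

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 200))
        res = gc.permute_slope_p(x, y, n_perm=200, seed=1)
        assert 0 < res.permutation_p <= 1


class TestCompareSlopes:
    def test_identical_fits_z_zero(self):
        f = RobustFitResult(1.0, 0.0, 0.1, 100)
        z, p = gc.compare_slopes_z(f, f)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_formula_example(self):
        f1 = RobustFitResult(1.0, 0.0, 0.1, 100)
        f2 = RobustFitResult(0.0, 0.0, 0.1, 100)
        z, p = gc.compare_slopes_z(f1, f2)
        assert z == pytest.approx(1.0 / np.sqrt(0.02))
        z_rev, p_rev = gc.compare_slopes_z(f2, f1)
        assert z_rev == pytest.approx(-z)
        assert p_rev == pytest.approx(p)

    def test_zero_combined_se_rejected(self):
        f = RobustFitResult(1.0, 0.0, 0.0, 100)
        with pytest.raises(ValueError, match="zero"):
            gc.compare_slopes_z(f, f)


class TestBHFDR:
    def test_hand_example(self):
        np.testing.assert_allclose(
            gc.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(gc.bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(gc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc.bh_fdr([0.5, 1.5])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(gc.bh_fdr(p), bh_oracle(p), atol=1e-12)


class TestThreshold:
    def _matrix(self, edges, modality="dMC"):
        return gc.ConnectivityMatrix.from_edges(
            np.asarray(edges, float), modality, "FT",
            tuple("abcd"[: int((1 + np.sqrt(1 + 8 * len(edges))) / 2)]),
        )

    def test_keeps_only_top_value(self):
        m = self._matrix([0.1, 0.2, 0.3, 0.4, 0.25, 0.15])  # 4 ROIs, 6 edges
        thr, masks = gc.threshold_top_fraction([m], fraction=0.25)
        assert masks[0].sum() == 2  # ceil(0.25 * 6)
        assert thr[0] == pytest.approx(0.3)

    def test_distinct_75_roi_matrix_keeps_694(self, small_cohort):
        _, ds = small_cohort
        m = mc_from_table(ds.metrics["FT"]).absolute()
        thr, masks = gc.threshold_top_fraction([m], fraction=0.25)
        assert masks[0].sum() == int(np.ceil(0.25 * 2775)) == 694

    def test_common_equals_adapted_for_identical_matrices(self, small_cohort):
        _, ds = small_cohort
        m = mc_from_table(ds.metrics["FT"]).absolute()
        thr_c, masks_c = gc.threshold_top_fraction([m, m], mode="common")
        thr_a, masks_a = gc.threshold_top_fraction([m, m], mode="adapted")
        assert thr_c == pytest.approx(thr_a)
        np.testing.assert_array_equal(masks_c[0], masks_a[0])

    def test_ties_at_threshold_all_kept(self):
        m = self._matrix([0.1, 0.4, 0.4, 0.2, 0.05, 0.0])
        _, masks = gc.threshold_top_fraction([m], fraction=0.25)
        assert masks[0].sum() == 2


class TestSubsetRegression:
    def test_report_structure_and_coupling_detected(self, labeling, small_cohort):
        _, ds = small_cohort
        mc = mc_from_table(ds.metrics["PT:ses1"]).absolute()
        s1 = [gc.subject_fc(gc.preprocess_timeseries(t)) for t in ds.timeseries["PT:ses1"]]
        fc = gc.group_fc(s1)
        df = gc.subset_regression_report(mc, fc, labeling, n_perm=100, seed=0)
        assert list(df["subset"]) == list(gc.stats.DEFAULT_SUBSETS)
        assert not df["skipped"].any()
        wb = df.set_index("subset").loc["whole-brain"]
        # shared planted blocks couple MC and FC
        assert wb["slope"] > 0
        assert wb["perm_p_bh"] <= 0.05

    def test_size_mismatch_rejected(self, labeling):
        small = gc.ConnectivityMatrix("MC", "FT", np.eye(3), ("a", "b", "c"))
        with pytest.raises(ValueError, match="labeling"):
            gc.subset_regression_report(small, small, labeling, n_perm=10)
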