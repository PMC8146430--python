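"""Assumption checks, nonparametric tests, FDR and the bin-by-bin analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sst

from connentropy import (
    ValidationError,
    WeightHistogram,
    analyze_entropy_table,
    assumption_checks,
    bh_fdr,
    bin_by_bin,
    kw_global,
    levene_test,
    lilliefors_test,
    pairwise_mwu,
    significant_bin_ranges,
    spearman_confound,
    weights_histogram,
)


class TestLilliefors:
    def test_type_one_error_calibrated(self):
        """Gaussian data should be rejected at ~alpha (Monte-Carlo oracle)."""
        rng = np.random.default_rng(11)
        n, reps = 50, 2000
        rejections = sum(
            lilliefors_test(rng.standard_normal(n), n_mc=10_000, seed=5).p_raw < 0.05
            for _ in range(reps)
        )
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_uniform(self):
        """Power grows with n; ~0.6 at n=100 and >0.9 at n=200 (both match a
        statsmodels Monte-Carlo oracle run at these sizes)."""
        rng = np.random.default_rng(12)
        reps = 200
        rej = {
            n: sum(
                lilliefors_test(rng.uniform(0, 1, n), n_mc=10_000,
                                seed=5).p_raw < 0.05
                for _ in range(reps)) / reps
            for n in (100, 200)
        }
        assert 0.45 <= rej[100] <= 0.75
        assert rej[200] > 0.9

    def test_matches_statsmodels_statistic(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        rng = np.random.default_rng(13)
        x = rng.standard_normal(80)
        d_sm, p_sm = sm_lf(x, dist="norm")
        r = lilliefors_test(x)
        assert r.statistic == pytest.approx(d_sm, abs=1e-12)
        if 0.01 < p_sm < 0.2:  # table range where statsmodels interpolates
            assert r.p_raw == pytest.approx(p_sm, abs=0.03)

    def test_zero_variance_flagged(self):
        with pytest.warns(RuntimeWarning):
            r = lilliefors_test(np.full(10, 1.0))
        assert np.isnan(r.p_raw)


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        r = levene_test({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert r.statistic == pytest.approx(0.0)

    def test_detects_unequal_spread(self):
        rng = np.random.default_rng(3)
        r = levene_test({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 5, 100)})
        assert r.p_raw < 0.01


class TestKruskalWallis:
    def test_identical_groups(self):
        r = kw_global({"a": [2.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 2.0]})
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_hand_rank_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        # ranks 1..9, rank sums 6, 15, 24 -> H = 12/(9*10) * sum(R^2/3) - 3*10
        expected = 12 / 90 * (36 + 225 + 576) / 3 - 30
        r = kw_global(groups)
        assert r.statistic == pytest.approx(expected, abs=1e-12)
        assert r.df == 2

    def test_asymptotic_p_close_to_permutation_p(self):
        rng = np.random.default_rng(21)
        groups = [rng.normal(0.3 * k, 1, 15) for k in range(3)]
        r = kw_global({f"g{k}": g for k, g in enumerate(groups)})
        pooled = np.concatenate(groups)
        sizes = [15, 15, 15]
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            parts = np.split(pooled, np.cumsum(sizes)[:-1])
            h = sst.kruskal(*parts).statistic
            count += h >= r.statistic
        p_perm = count / n_perm
        assert abs(r.p_raw - p_perm) < 0.02

    def test_invariant_to_monotone_transform(self, rng):
        groups = {k: rng.normal(k, 1, 10) for k in range(3)}
        r1 = kw_global(groups)
        r2 = kw_global({k: np.exp(v) for k, v in groups.items()})
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        r = pairwise_mwu([1.0, 1.0, 1.0], [1.0, 1.0])
        assert r.p_raw == 1.0

    def test_complete_separation_u_zero(self):
        r = pairwise_mwu([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0

    def test_asymptotic_close_to_exact_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.8, 1, 9)
            p_asym = pairwise_mwu(a, b).p_raw
            p_exact = sst.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
            assert abs(p_asym - p_exact) < 0.02


class TestSpearman:
    def test_strictly_increasing_gives_plus_one(self):
        r = spearman_confound([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.statistic == pytest.approx(1.0)

    def test_strictly_decreasing_gives_minus_one(self):
        r = spearman_confound([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.statistic == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
        rho = spearman_confound(x, y).statistic
        rx = sst.rankdata(x)
        ry = sst.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_covariate_flagged(self):
        with pytest.warns(RuntimeWarning):
            r = spearman_confound([1, 2, 3, 4, 5], [2, 2, 2, 2, 2])
        assert np.isnan(r.statistic)


class TestBhFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_equal_ps_unchanged(self):
        adj, _ = bh_fdr([0.04, 0.04, 0.04])
        assert np.allclose(adj, 0.04)

    def test_step_up_closed_form(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30))
    def test_adjusted_monotone_in_raw(self, ps):
        adj, _ = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)


class TestAssumptionChecks:
    def test_nonnormal_data_recommends_nonparametric(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.uniform(0, 1, 60), "b": rng.uniform(0, 1, 60),
                  "c": rng.uniform(0, 1, 60)}
        rep = assumption_checks(groups)
        assert rep.recommend_nonparametric

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match=">= 4"):
            assumption_checks({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0, 4.0]})


from helpers import histogram_cohort as _histogram_cohort


class TestBinByBin:
    def test_identical_groups_no_significant_bins(self):
        rng = np.random.default_rng(6)
        hists = {g: _histogram_cohort(rng, ("beta", 2, 6), 12) for g in "abc"}
        results = bin_by_bin(hists, bands=["alpha"])
        assert len(results) == 40
        assert not any(r.significant(0.05) for r in results)

    def test_injected_single_bin_shift_detected_with_power(self):
        """+0.05 relative probability in one bin is flagged reliably."""
        rng = np.random.default_rng(8)
        flags = 0
        reps = 30
        target_bin = 14  # [0.35, 0.375)
        for _ in range(reps):
            base = {g: _histogram_cohort(rng, ("beta", 2, 6), 30) for g in "ab"}
            shifted = []
            for h in base["b"]:
                q = h.q.copy()
                q[target_bin] += 0.05
                shifted.append(WeightHistogram(q / q.sum(), h.bin_edges, band="alpha"))
            results = bin_by_bin({"a": base["a"], "b": shifted}, bands=["alpha"])
            flags += results[target_bin].significant(0.05)
        assert flags / reps > 0.8

    def test_mismatched_bin_counts_rejected(self, rng):
        h40 = weights_histogram(rng.uniform(0, 1, 100), 40, band="alpha")
        h20 = weights_histogram(rng.uniform(0, 1, 100), 20, band="alpha")
        with pytest.raises(ValidationError, match="bin counts"):
            bin_by_bin({"a": [h40] * 3, "b": [h20] * 3}, bands=["alpha"])

    def test_significant_ranges_are_contiguous_merges(self):
        from connentropy.containers import BinComparisonResult, TestResult
        bins = []
        for i, p in enumerate([0.001, 0.001, 0.5, 0.001, 0.9]):
            bins.append(BinComparisonResult(
                band="alpha", bin_index=i, bin_low=i * 0.025,
                bin_high=(i + 1) * 0.025,
                result=TestResult("kw", 1.0, p, p_adjusted=p)))
        ranges = significant_bin_ranges(bins)["alpha"]
        assert len(ranges) == 2
        assert ranges[0] == pytest.approx((0.0, 0.05))
        assert ranges[1] == pytest.approx((0.075, 0.1))


class TestFullProcedureTypeIError:
    def test_null_cohorts_rarely_flag_any_bin(self):
        """Familywise false-positive rate of KW+BH bin-by-bin under the null."""
        rng = np.random.default_rng(9)
        n_cohorts = 500
        false_cohorts = 0
        for _ in range(n_cohorts):
            hists = {g: _histogram_cohort(rng, ("beta", 2, 6), 8,
                                          n_trials=3, n_nodes=16)
                     for g in "abc"}
            results = bin_by_bin(hists, bands=["alpha"])
            false_cohorts += any(r.significant(0.05) for r in results)
        assert false_cohorts / n_cohorts <= 0.07

    def test_group_label_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        groups = {g: rng.normal(0, 1, 12) for g in ("a", "b", "c")}
        r1 = kw_global(groups)
        r2 = kw_global({f"z_{k}": v for k, v in groups.items()})
        assert r1.statistic == r2.statistic


class TestAnalyzeEntropyTable:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(14)
        rows = []
        for band, delta in [("alpha", 0.08), ("gamma", 0.0)]:
            for g, shift in [("control", delta), ("mci", delta / 2), ("ad", 0.0)]:
                for i in range(20):
                    rows.append({"subject_id": f"{g}-{i}", "group": g,
                                 "band": band,
                                 "se": 0.7 + shift + rng.normal(0, 0.03)})
        return pd.DataFrame(rows)

    def test_hierarchy_restricts_followups_to_significant_bands(self, table):
        report = analyze_entropy_table(table)
        assert "alpha" in report.analyzed_bands
        assert "gamma" not in report.analyzed_bands
        assert set(report.pairwise_tests) == set(report.analyzed_bands)

    def test_pairwise_orientation_and_fdr(self, table):
        report = analyze_entropy_table(table)
        pairs = report.pairwise_tests["alpha"]
        assert set(pairs) == {"control-mci", "control-ad", "mci-ad"}
        assert pairs["control-ad"].p_adjusted >= pairs["control-ad"].p_raw

    def test_confound_check_runs_per_band(self, table):
        rng = np.random.default_rng(15)
        cov = pd.DataFrame({
            "subject_id": table["subject_id"].unique(),
            "age": rng.uniform(60, 85, table["subject_id"].nunique()),
        })
        report = analyze_entropy_table(table, covariates=cov)
        assert "alpha:age" in report.confounds
        assert abs(report.confounds["alpha:age"].statistic) < 0.5

    def test_report_serializes(self, table):
        report = analyze_entropy_table(table)
        d = report.to_dict()
        assert "tests" in d and len(d["tests"]) > 0
        frame = report.to_frame()
        assert {"kind", "band", "p_raw", "p_adjusted"}.issubset(frame.columns)
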