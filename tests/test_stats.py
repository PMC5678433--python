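"""Cohort statistics: matching optimality, ANCOVA, exact tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortexflow as cf


def brute_force_total_distance(cases, pool):
    """Exhaustive minimum over all injective case->control assignments."""
    ca = cases[["ga_wk", "pma_wk"]].to_numpy(float)
    po = pool[["ga_wk", "pma_wk"]].to_numpy(float)
    best = np.inf
    for perm in itertools.permutations(range(len(po)), len(ca)):
        d = sum(np.linalg.norm(ca[i] - po[j]) for i, j in enumerate(perm))
        best = min(best, d)
    return best


def toy_table(ga_cases, pma_cases, ga_pool, pma_pool):
    cases = pd.DataFrame(
        {"subject_id": [f"c{i}" for i in range(len(ga_cases))],
         "ga_wk": ga_cases, "pma_wk": pma_cases}
    )
    pool = pd.DataFrame(
        {"subject_id": [f"p{i}" for i in range(len(ga_pool))],
         "ga_wk": ga_pool, "pma_wk": pma_pool}
    )
    return cases, pool


class TestMatching:
    def test_exact_duplicates_give_zero_distance(self):
        rng = np.random.default_rng(0)
        ga, pma = rng.normal(38, 1, 6), rng.normal(39, 1, 6)
        cases, pool = toy_table(ga, pma, ga, pma)
        res = cf.match_controls(cases, pool)
        assert res.total_distance == pytest.approx(0.0, abs=1e-12)
        assert (res.pairs.distance == 0).all()

    def test_matches_brute_force_on_5x7(self):
        rng = np.random.default_rng(42)
        cases, pool = toy_table(
            rng.normal(38, 1, 5), rng.normal(39, 1, 5),
            rng.normal(38, 1, 7), rng.normal(39, 1, 7),
        )
        res = cf.match_controls(cases, pool)
        assert res.total_distance == pytest.approx(
            brute_force_total_distance(cases, pool), rel=1e-12
        )

    def test_optimal_for_random_pools_up_to_8(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_case = int(rng.integers(2, 6))
            n_pool = int(rng.integers(n_case, 9))
            cases, pool = toy_table(
                rng.normal(38, 1, n_case), rng.normal(39, 1, n_case),
                rng.normal(38, 1, n_pool), rng.normal(39, 1, n_pool),
            )
            res = cf.match_controls(cases, pool)
            assert res.total_distance == pytest.approx(
                brute_force_total_distance(cases, pool), rel=1e-9
            )

    def test_axis_scaling_leaves_pairing_unchanged(self):
        rng = np.random.default_rng(3)
        cases, pool = toy_table(
            rng.normal(38, 1, 4), rng.normal(39, 1, 4),
            rng.normal(38, 1, 6), rng.normal(39, 1, 6),
        )
        res1 = cf.match_controls(cases, pool)
        for df in (cases, pool):
            df[["ga_wk", "pma_wk"]] *= 3.0
        res2 = cf.match_controls(cases, pool)
        pd.testing.assert_frame_equal(
            res1.pairs[["case_id", "control_id"]], res2.pairs[["case_id", "control_id"]]
        )

    def test_insufficient_pool_rejected(self):
        cases, pool = toy_table([38, 39, 38.5], [39, 39, 39], [38], [39])
        with pytest.raises(ValueError, match="pool"):
            cf.match_controls(cases, pool)


class TestAncova:
    def test_recovers_injected_group_offset(self):
        spec = cf.CohortSpec(group_gmv_offset_ml=-27.0, gmv_noise_sd_ml=3.0, seed=2)
        res = cf.ancova_group_effect(cf.make_cohort(spec), "gmv_ml")
        assert res.ci_low < -27.0 < res.ci_high
        assert res.n_case == res.n_control == 30

    def test_null_outcome_gives_zero_effect(self):
        table = cf.make_cohort(cf.CohortSpec(seed=4))
        table["flat"] = 5.0
        res = cf.ancova_group_effect(table, "flat")
        assert res.group_effect == pytest.approx(0.0, abs=1e-10)
        assert res.group_p == pytest.approx(1.0)

    def test_extra_covariates_do_not_shift_a_clean_effect(self):
        spec = cf.CohortSpec(group_gmv_offset_ml=-20.0, gmv_noise_sd_ml=3.0, seed=6)
        table = cf.make_cohort(spec)
        rng = np.random.default_rng(6)
        table["ventilation_days"] = rng.integers(0, 10, len(table)).astype(float)
        plain = cf.ancova_group_effect(table, "gmv_ml")
        extra = cf.ancova_group_effect(table, "gmv_ml", extra_covariates=("ventilation_days",))
        assert extra.group_effect == pytest.approx(plain.group_effect, abs=2.0)
        assert extra.covariates == ("pma_wk", "ventilation_days")

    def test_collinear_design_rejected(self):
        table = cf.make_cohort(cf.CohortSpec(seed=8))
        table["pma_copy"] = table["pma_wk"]
        with pytest.raises(ValueError, match="collinear"):
            cf.ancova_group_effect(table, "gmv_ml", extra_covariates=("pma_copy",))

    def test_listwise_deletion_is_counted(self):
        table = cf.make_cohort(cf.CohortSpec(seed=9))
        table.loc[table.index[:4], "gmv_ml"] = np.nan
        res = cf.ancova_group_effect(table, "gmv_ml")
        assert res.n_dropped == 4

    def test_type_one_error_calibrated_under_null(self):
        # no group effect: rejection rate at alpha=0.05 should be ~5%
        rejections = 0
        n_rep = 400
        for rep in range(n_rep):
            spec = cf.CohortSpec(
                group_gi_offset=0.0, group_gmv_offset_ml=0.0, seed=20_000 + rep
            )
            res = cf.ancova_group_effect(cf.make_cohort(spec), "gmv_ml")
            rejections += res.group_p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestLinreg:
    def test_perfect_line(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        res = cf.linreg(t, "x", "y")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        res1 = cf.linreg(t, "x", "y")
        res2 = cf.linreg(t.sample(frac=1.0, random_state=5), "x", "y")
        assert res1.slope == pytest.approx(res2.slope, rel=1e-12)
        assert res1.intercept == pytest.approx(res2.intercept, abs=1e-12)
        assert res1.r_squared == pytest.approx(res2.r_squared, rel=1e-12)
        assert res1.n == res2.n

    def test_r_squared_equals_squared_pearson(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame({"x": rng.normal(size=30)})
        t["y"] = 0.5 * t.x + rng.normal(size=30)
        from scipy.stats import pearsonr

        res = cf.linreg(t, "x", "y")
        assert res.r_squared == pytest.approx(pearsonr(t.x, t.y)[0] ** 2, abs=1e-12)

    def test_zero_variance_x_rejected(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="variance"):
            cf.linreg(t, "x", "y")


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_threshold(self, alpha, m, expected):
        assert cf.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cf.bonferroni_threshold(0.0, 4)
        with pytest.raises(ValueError):
            cf.bonferroni_threshold(0.05, 0)


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        # U = 0; two-sided p = 2 / C(6,3) = 0.1
        res = cf.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_p_one(self):
        res = cf.mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0
        assert res.all_tied

    def test_branches_agree_at_moderate_n(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            xs = rng.normal(0.0, 1.0, 15)
            ys = rng.normal(0.5, 1.0, 15)
            exact = cf.mann_whitney(xs, ys)  # 225 <= 400, no ties -> exact
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(xs, ys, alternative="two-sided", method="asymptotic")
            assert exact.method == "exact"
            assert abs(exact.p_value - approx.pvalue) < 0.01

    def test_large_or_tied_samples_use_approximation(self):
        rng = np.random.default_rng(11)
        res = cf.mann_whitney(rng.normal(size=25), rng.normal(size=25))
        assert res.method == "asymptotic"
        res = cf.mann_whitney([1, 2, 2, 3], [2, 4, 5])
        assert res.method == "asymptotic"


class TestFisherExact:
    def test_male_sex_table(self):
        # 16 of 30 vs 8 of 30 -> p = 0.06 to two decimals
        assert round(cf.fisher_exact(16, 14, 8, 22), 2) == 0.06

    def test_balanced_table_p_one(self):
        assert cf.fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    def test_symmetric_under_row_and_column_swap(self):
        assert cf.fisher_exact(16, 14, 8, 22) == pytest.approx(
            cf.fisher_exact(22, 8, 14, 16)
        )

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            cf.fisher_exact(-1, 2, 3, 4)


class TestRepeatability:
    def test_identical_readings(self):
        x = np.arange(10.0)
        res = cf.repeatability(x, x)
        assert res.r_squared == pytest.approx(1.0)

    def test_equal_noise_gives_r2_about_half(self):
        # second = first + independent noise of equal variance -> R^2 ~ 0.5
        r2 = []
        rng = np.random.default_rng(12)
        for _ in range(200):
            first = rng.normal(0, 1, 24)
            second = first + rng.normal(0, 1, 24)
            r2.append(cf.repeatability(first, second).r_squared)
        assert 0.4 < float(np.mean(r2)) < 0.6

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        a = rng.normal(70, 5, 24)
        b = a + rng.normal(0, 2, 24)
        assert cf.repeatability(a, b).r_squared == pytest.approx(
            cf.repeatability(2 * a + 1, b / 3 - 2).r_squared, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cf.repeatability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestExclusions:
    def test_study_intake_accounting(self):
        # 33 recruited, 2 with arterial stroke, 1 undatable -> 30 retained
        table = pd.DataFrame(
            {
                "subject_id": [f"s{i:02d}" for i in range(33)],
                "ga_wk": [38.0] * 32 + [np.nan],
                "arterial_stroke": [True, True] + [False] * 31,
            }
        )
        kept, accounting = cf.apply_exclusions(table)
        assert accounting == {
            "recruited": 33,
            "excluded_stroke": 2,
            "excluded_undatable": 1,
            "retained": 30,
        }
        assert len(kept) == 30

    def test_no_flags_keeps_everyone(self):
        table = pd.DataFrame({"subject_id": ["a", "b"], "ga_wk": [38.0, 39.0]})
        kept, acc = cf.apply_exclusions(table)
        assert acc["retained"] == 2


class TestCountPercent:
    @pytest.mark.parametrize("k,n,pct", [(5, 14, 36), (14, 30, 47), (1, 3, 33), (0, 5, 0)])
    def test_rounded_percent(self, k, n, pct):
        assert cf.count_percent(k, n) == (k, pct)

    def test_invalid(self):
        with pytest.raises(ValueError):
            cf.count_percent(5, 0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8),
)
def test_mann_whitney_p_always_valid(xs, ys):
    res = cf.mann_whitney(xs, ys)
    assert 0.0 <= res.p_value <= 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
def test_fisher_p_always_valid(a, b, c, d):
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        return
    assert 0.0 <= cf.fisher_exact(a, b, c, d) <= 1.0
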