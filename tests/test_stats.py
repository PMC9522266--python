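from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats as sps

from reacharc import (
    DegenerateStatisticError,
    InsufficientDataError,
    NoInformationError,
    analyze_experiment,
    mann_whitney,
    one_sample_t,
    pearson_corr,
    permutation_slope_test,
    shapiro_wilk,
    wilcoxon_paired,
)

from conftest import make_log
from _oracles import (
    exact_permutation_slope_p,
    mann_whitney_enumeration,
    signed_rank_enumeration,
    u_count_direct,
)


class TestShapiroWilk:
    # frozen independent oracle: R 4.3.3 shapiro.test on the same vectors
    R_CASES = [
        ([148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236],
         0.7888146948, 0.0067038141),
        ([2.1, 3.4, 1.9, 5.6, 3.3, 2.8, 4.1, 3.0, 2.2, 3.9, 4.4, 2.6],
         0.9503582978, 0.6422290468),
    ]

    @pytest.mark.parametrize("values,w_r,p_r", R_CASES)
    def test_matches_r_reference(self, values, w_r, p_r):
        res = shapiro_wilk(values)
        assert res.statistic == pytest.approx(w_r, abs=1e-3)
        assert res.p == pytest.approx(p_r, abs=1e-4)

    def test_null_p_uniform(self):
        gen = np.random.default_rng(1)
        ps = [shapiro_wilk(gen.standard_normal(500)).p for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_power_against_exponential(self):
        gen = np.random.default_rng(2)
        rejected = sum(
            shapiro_wilk(gen.exponential(1.0, size=100)).p < 0.001
            for _ in range(100)
        )
        assert rejected >= 99

    def test_degenerate_and_bounds(self):
        with pytest.raises(DegenerateStatisticError):
            shapiro_wilk([1.0] * 10)
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])


class TestWilcoxonPaired:
    def test_identical_samples_raise(self):
        with pytest.raises(NoInformationError):
            wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_toy_n6_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.5, 1.0, 5.0, 4.2, 8.0, 6.3]
        res = wilcoxon_paired(x, y)
        d = np.array(y) - np.array(x)
        t_obs, mu, var, _ = signed_rank_enumeration(d)
        assert res.statistic == pytest.approx(t_obs)
        assert res.z == pytest.approx((t_obs - mu) / math.sqrt(var), abs=1e-10)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(res.z)), abs=1e-12)

    def test_tie_corrected_variance_matches_enumeration(self, rng):
        # integer-valued differences force midranks and tie corrections
        for _ in range(25):
            n = int(rng.integers(3, 9))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            d = y - x
            d = d[d != 0]
            if d.size == 0:
                continue
            res = wilcoxon_paired(np.zeros(d.size), d)
            _, mu, var, _ = signed_rank_enumeration(d)
            assert res.details["sigma_T"] == pytest.approx(
                math.sqrt(var), abs=1e-10
            )
            assert res.z == pytest.approx(
                (res.statistic - mu) / math.sqrt(var), abs=1e-10
            )

    def test_orientation_complementarity(self, rng):
        # tie-free: T(x,y) + T(y,x) = n(n+1)/2
        for _ in range(20):
            n = int(rng.integers(2, 10))
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n) * 0.7 + 0.2
            a = wilcoxon_paired(x, y)
            b = wilcoxon_paired(y, x)
            assert a.statistic + b.statistic == pytest.approx(a.n * (a.n + 1) / 2)
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_agrees_with_scipy_asymptotic(self, rng):
        x = rng.standard_normal(15)
        y = x + 0.4 + rng.standard_normal(15) * 0.5
        ours = wilcoxon_paired(x, y)
        ref = sps.wilcoxon(y, x, correction=False, method="approx")
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-10)


class TestMannWhitney:
    def test_complete_separation(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 4.0  # U for the second group
        assert res.details["U_first"] == 0.0

    def test_toy_with_tie_matches_enumeration(self):
        x = [1.0, 2.0, 3.0, 3.0]
        y = [3.0, 4.0, 5.0, 6.0]
        res = mann_whitney(x, y)
        u_obs, mu, var, _ = mann_whitney_enumeration(x, y)
        assert res.statistic == pytest.approx(u_obs)
        assert res.statistic == pytest.approx(u_count_direct(x, y))
        assert res.z == pytest.approx((u_obs - mu) / math.sqrt(var), abs=1e-10)

    def test_u_orientations_sum_to_n1n2(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, size=2)
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            res = mann_whitney(x, y)
            assert res.details["U_first"] + res.details["U_second"] == pytest.approx(
                n1 * n2
            )

    def test_agrees_with_scipy_asymptotic(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(25) + 0.5
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(y, x, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert ours.statistic == pytest.approx(float(ref.statistic))
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-10)

    def test_empty_group_raises(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


class TestPearsonCorr:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_corr(x, [2 * v + 1 for v in x]).statistic == pytest.approx(1.0)
        assert pearson_corr(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_matches_covariance_oracle_and_scipy(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        res = pearson_corr(x, y)
        r_manual = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert res.statistic == pytest.approx(r_manual, abs=1e-12)
        ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(float(ref.pvalue), abs=1e-12)
        assert res.details["df"] == 18

    def test_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestOneSampleT:
    def test_symmetric_sample_t_zero(self):
        res = one_sample_t([-1.0, 0.0, 1.0], mu0=0.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_mean_equals_mu0(self):
        assert one_sample_t([1.0, 2.0, 3.0], mu0=2.0).statistic == pytest.approx(0.0)

    def test_matches_scipy(self, rng):
        v = rng.standard_normal(20) + 0.3
        res = one_sample_t(v)
        ref = sps.ttest_1samp(v, 0.0)
        assert res.statistic == pytest.approx(float(ref.statistic), abs=1e-12)
        assert res.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_low_power_near_null_slope_scenario(self):
        # slopes ~ N(0.002, 0.01), n = 20: rejection rate should sit near the
        # analytic t-test power (~13-14%), i.e. an expected null-ish outcome
        gen = np.random.default_rng(8)
        rejections = sum(
            one_sample_t(gen.normal(0.002, 0.01, size=20)).p < 0.05
            for _ in range(2000)
        )
        assert 0.09 < rejections / 2000 < 0.19

    def test_zero_sd_raises(self):
        with pytest.raises(DegenerateStatisticError):
            one_sample_t([2.0, 2.0, 2.0])


class TestPermutationSlope:
    def test_constant_series(self):
        res = permutation_slope_test([3.0] * 10, n_permutations=500, seed=0)
        assert res.observed_slope == pytest.approx(0.0, abs=1e-15)
        assert res.p == 1.0

    def test_add_one_bounds(self):
        res = permutation_slope_test(list(range(20)), n_permutations=999, seed=1)
        assert 1.0 / 1000 <= res.p <= 1.0

    def test_monotone_series_extreme(self):
        res = permutation_slope_test(
            [float(i) for i in range(1, 51)], n_permutations=10_000, seed=2
        )
        assert res.p <= 0.001

    def test_matches_exact_enumeration_n5(self):
        y = [0.3, 1.7, 0.9, 2.8, 1.1]
        exact = exact_permutation_slope_p(y)
        n_perm = 4000
        res = permutation_slope_test(y, n_permutations=n_perm, seed=3)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p - exact) <= 3 * se + 2.0 / (n_perm + 1)

    def test_seeded_determinism(self):
        y = list(np.random.default_rng(4).uniform(0, 5, 30))
        a = permutation_slope_test(y, n_permutations=200, seed=9)
        b = permutation_slope_test(y, n_permutations=200, seed=9)
        assert a == b


class TestAnalyzeExperiment:
    def _cohort(self, n=6, n_trials=30, seed=0):
        from reacharc import ProtocolConfig, exp1_population, simulate_cohort

        return simulate_cohort(
            n,
            ProtocolConfig(n_trials_per_condition=n_trials, rng_seed=seed),
            exp1_population(),
            seed=seed,
        )

    def test_paired_report_structure(self):
        rep = analyze_experiment(self._cohort(), design="paired", seed=1)
        assert {"accuracy_wilcoxon", "precision_wilcoxon", "reach_time_wilcoxon",
                "accuracy_first25_wilcoxon", "slope_t_visible",
                "slope_t_invisible"} <= set(rep.tests)
        assert "corr_accuracy_precision_visible" in rep.tests
        assert rep.group["visible"]["n"] == 6
        assert rep.n_tests >= 8
        # serialization stays JSON-safe
        import json

        json.dumps(rep.to_dict())

    def test_individual_battery(self):
        logs = self._cohort(n=1, n_trials=40)
        rep = analyze_experiment(
            logs, design="individual", n_permutations=300, seed=2
        )
        battery = rep.per_participant[logs[0].participant_id]
        assert {"error_mannwhitney", "reach_time_mannwhitney",
                "error_first25_mannwhitney", "slope_perm_visible",
                "slope_perm_invisible"} == set(battery)

    def test_first25_equals_truncated_logs(self):
        logs = self._cohort(n=5, n_trials=60, seed=3)
        rep25 = analyze_experiment(logs, design="paired", first_n=25, seed=4)
        truncated = [
            make_log(
                {
                    c: [t.error_deg for t in log.condition_trials(c)][:25]
                    for c in ("visible", "invisible")
                },
                times_by_condition={
                    c: [t.reach_time_ms for t in log.condition_trials(c)][:25]
                    for c in ("visible", "invisible")
                },
                participant_id=log.participant_id,
            )
            for log in logs
        ]
        rep_trunc = analyze_experiment(truncated, design="paired", seed=4)
        for key in ("accuracy_wilcoxon", "precision_wilcoxon"):
            assert rep25.tests[key].statistic == pytest.approx(
                rep_trunc.tests[key].statistic
            )
            assert rep25.tests[key].p == pytest.approx(rep_trunc.tests[key].p)

    def test_paired_needs_two_participants(self):
        with pytest.raises(InsufficientDataError):
            analyze_experiment(self._cohort(n=1), design="paired")

    def test_mixed_experiments_rejected(self):
        a = make_log({"visible": [1.0] * 5, "invisible": [2.0] * 5})
        b = make_log(
            {"standard": [1.0] * 5, "delayed": [2.0] * 5},
            experiment="memory_delay",
            participant_id="T02",
        )
        with pytest.raises(ValueError):
            analyze_experiment([a, b], design="paired")
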