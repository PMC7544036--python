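"""Survival-analysis wrappers against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from irgps import cox_fit, logrank_test, rmst, score_by_mutation, subgroup_analysis
from irgps.simulate import SimulationConfig, simulate_cohort


def _surv(times, events, index=None, **covariates):
    index = index or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame({"os_time": times, "event": events, **covariates}, index=index)


def logrank_oracle(times, events, labels):
    """Two-group log-rank chi-square by explicit risk-set enumeration."""
    o_minus_e, var = 0.0, 0.0
    for et in sorted(set(times[events == 1])):
        at_risk = times >= et
        n, n1 = at_risk.sum(), (at_risk & (labels == 1)).sum()
        d = ((times == et) & (events == 1)).sum()
        d1 = ((times == et) & (events == 1) & (labels == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def efron_partial_loglik(beta, times, events, z):
    """Efron partial log-likelihood, written directly from its definition."""
    ll = 0.0
    for et in sorted(set(times[events == 1])):
        deaths = (times == et) & (events == 1)
        d = deaths.sum()
        risk = times >= et
        sum_risk = np.sum(np.exp(beta * z[risk]))
        sum_deaths = np.sum(np.exp(beta * z[deaths]))
        ll += beta * z[deaths].sum()
        for j in range(d):
            ll -= np.log(sum_risk - (j / d) * sum_deaths)
    return ll


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([3.0, 5.0, 9.0, 3.0, 5.0, 9.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        surv = _surv(times, events)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=surv.index)
        res = logrank_test(surv, groups)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        # observed equals expected in every group exactly when statistic is 0
        assert res.groups["observed"].tolist() == pytest.approx(res.groups["expected"].tolist())

    def test_matches_risk_set_oracle(self, six_subject_survival):
        labels = pd.Series([1, 1, 0, 1, 0, 0], index=six_subject_survival.index)
        res = logrank_test(six_subject_survival, labels.map({1: "one", 0: "zero"}))
        times = six_subject_survival["os_time"].to_numpy()
        events = six_subject_survival["event"].to_numpy()
        assert res.statistic == pytest.approx(logrank_oracle(times, events, labels.to_numpy()), abs=1e-10)
        assert res.df == 1

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(1)
        n = 200
        times = np.concatenate([rng.exponential(10, n), rng.exponential(40, n)]) + 0.01
        surv = _surv(times, np.ones(2 * n, int))
        groups = pd.Series(["high"] * n + ["low"] * n, index=surv.index)
        assert logrank_test(surv, groups).p < 1e-6

    def test_single_group_rejected(self, six_subject_survival):
        with pytest.raises(ValueError, match="two nonempty groups"):
            logrank_test(six_subject_survival, pd.Series(["x"] * 6, index=six_subject_survival.index))

    def test_invariant_to_monotone_time_rescaling(self, six_subject_survival):
        labels = pd.Series(list("aabbab"), index=six_subject_survival.index)
        res1 = logrank_test(six_subject_survival, labels)
        rescaled = six_subject_survival.assign(os_time=six_subject_survival["os_time"] ** 1.7)
        res2 = logrank_test(rescaled, labels)
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-12)


class TestCoxFit:
    def test_tiny_dataset_matches_grid_maximum(self):
        # 5 subjects with a tie: grid-maximise the Efron partial likelihood
        times = np.array([2.0, 3.0, 3.0, 5.0, 8.0])
        events = np.array([1, 1, 1, 0, 1])
        z = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        surv = _surv(times, events, z=z)
        res = cox_fit(surv, which="z")
        grid = np.linspace(-3, 3, 20001)
        ll = [efron_partial_loglik(b, times, events, z) for b in grid]
        assert res.summary.loc["z", "coef"] == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)

    def test_hr_equivariance_under_negation(self):
        rng = np.random.default_rng(4)
        n = 120
        z = rng.normal(size=n)
        times = rng.exponential(20, n) * np.exp(-0.5 * z) + 0.01
        surv = _surv(times, np.ones(n, int), z=z, neg_z=-z)
        hr = cox_fit(surv, which="z").summary.loc["z", "hazard_ratio"]
        hr_neg = cox_fit(surv, which="neg_z").summary.loc["neg_z", "hazard_ratio"]
        assert hr * hr_neg == pytest.approx(1.0, rel=1e-6)

    def test_ci_brackets_hr_and_null_covers_one(self):
        rng = np.random.default_rng(8)
        n = 150
        surv = _surv(rng.exponential(20, n) + 0.01, (rng.uniform(size=n) < 0.7).astype(int),
                     z=rng.normal(size=n))
        row = cox_fit(surv, which="z").summary.loc["z"]
        assert row["ci_low"] <= row["hazard_ratio"] <= row["ci_high"]
        assert row["ci_low"] < 1.0 < row["ci_high"]  # null covariate

    def test_duplicated_covariate_rejected(self):
        surv = _surv([1.0, 2.0, 3.0], [1, 1, 1], z=[0.0, 1.0, 0.5])
        with pytest.raises(ValueError, match="duplicate"):
            cox_fit(surv, which=["z", "z"])

    def test_collinear_covariates_rejected(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], z=[0.0, 1.0, 0.5, 0.2],
                     z2=[0.0, 2.0, 1.0, 0.4])
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(surv, which=["z", "z2"])

    def test_complete_case_handling(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 0, 1, 1, 0],
                     z=[0.1, np.nan, 0.5, 0.9, 0.3, np.nan])
        res = cox_fit(surv, which="z")
        assert res.n == 4

    def test_multivariate_recovers_both_signs(self):
        expr, clin, truth = simulate_cohort(SimulationConfig(seed=3, n_samples=400))
        clin = clin.assign(eta=truth["eta"].to_numpy())
        res = cox_fit(clin, which=["eta", "age"])
        assert res.summary.loc["eta", "coef"] > 0.5
        assert abs(res.summary.loc["age", "coef"]) < 0.05


class TestScoreByMutation:
    def test_identical_groups_no_difference(self):
        scores = pd.Series(np.tile([0.1, 0.5, 0.9, 1.3], 2), index=[f"s{i}" for i in range(8)])
        flags = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=scores.index)
        out = score_by_mutation(scores, flags)
        assert out["mean_mut"] == pytest.approx(out["mean_wt"])
        assert out["t_p"] == pytest.approx(1.0)

    def test_wilcoxon_matches_exact_enumeration(self):
        scores = pd.Series([1.3, 0.2, 2.9, 0.7, 1.9, 0.4, 3.3, 2.1],
                           index=[f"s{i}" for i in range(8)])
        flags = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=scores.index)
        out = score_by_mutation(scores, flags)
        # exhaustively enumerate all C(8,4) rank assignments
        ranks = scores.rank().to_numpy()
        observed = ranks[:4].sum()
        total = list(
            itertools.combinations(range(8), 4)
        )
        stats_all = np.array([ranks[list(c)].sum() for c in total])
        centre = ranks.sum() / 2
        p_exact = np.mean(np.abs(stats_all - centre) >= abs(observed - centre) - 1e-12)
        assert out["wilcoxon_p"] == pytest.approx(p_exact, abs=1e-10)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(12)
        scores = pd.Series(np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)]),
                           index=[f"s{i}" for i in range(100)])
        flags = pd.Series([0] * 50 + [1] * 50, index=scores.index)
        out = score_by_mutation(scores, flags)
        assert out["t_p"] < 0.01 and out["wilcoxon_p"] < 0.01

    def test_empty_group_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="nonempty"):
            score_by_mutation(scores, pd.Series([1, 1], index=scores.index))


class TestRMST:
    def test_no_events_equals_tau(self):
        surv = _surv([20.0, 30.0], [0, 0])
        groups = pd.Series(["a", "b"], index=surv.index)
        out = rmst(surv, groups, tau=10.0)
        assert out["rmst"]["a"] == pytest.approx(10.0)

    def test_single_death_is_unit_step_area(self):
        surv = _surv([5.0, 25.0], [1, 0])
        groups = pd.Series(["g", "h"], index=surv.index)
        out = rmst(surv, groups, tau=10.0)
        assert out["rmst"]["g"] == pytest.approx(5.0)

    def test_identical_groups_ratio_one(self):
        times = [3.0, 6.0, 9.0]
        surv = _surv(times + times, [1, 0, 1, 1, 0, 1])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=surv.index)
        assert rmst(surv, groups, tau=8.0)["ratio"] == pytest.approx(1.0)

    def test_nonpositive_tau_rejected(self, six_subject_survival):
        groups = pd.Series(list("aabbab"), index=six_subject_survival.index)
        with pytest.raises(ValueError, match="positive"):
            rmst(six_subject_survival, groups, tau=0.0)


class TestSubgroupAnalysis:
    def test_effect_present_in_both_strata(self):
        expr, clin, truth = simulate_cohort(SimulationConfig(seed=21, n_samples=500))
        scores = truth["eta"]
        cutoff = float(scores.median())
        out = subgroup_analysis(clin, scores, cutoff, "braf_mut")
        assert set(out) == {0, 1}
        for stratum in out.values():
            assert stratum["logrank"].p < 0.05
            assert stratum["cox"].summary.loc["risk_score", "hazard_ratio"] > 1.0

    def test_single_value_stratum_matches_unstratified(self, six_subject_survival):
        surv = six_subject_survival.assign(flag=1)
        scores = pd.Series([2.0, 1.5, 0.3, 0.8, -0.6, -1.1], index=surv.index)
        out = subgroup_analysis(surv, scores, 0.5, "flag")
        assert list(out) == [1]
        from irgps import assign_groups

        direct = logrank_test(six_subject_survival, assign_groups(scores, 0.5))
        assert out[1]["logrank"].statistic == pytest.approx(direct.statistic)

    def test_degenerate_stratum_reports_na(self):
        surv = _surv([2.0, 3.0, 4.0, 9.0], [1, 1, 1, 1], flag=[0, 0, 1, 1])
        scores = pd.Series([5.0, 6.0, 7.0, 8.0], index=surv.index)
        with pytest.warns(UserWarning, match="NA"):
            out = subgroup_analysis(surv, scores, 0.0, "flag")  # every score > 0 -> one group
        assert out[0]["logrank"] is None and out[0]["cox"] is None

    def test_missing_stratum_column_rejected(self, six_subject_survival):
        scores = pd.Series(np.arange(6.0), index=six_subject_survival.index)
        with pytest.raises(KeyError, match="nope"):
            subgroup_analysis(six_subject_survival, scores, 0.5, "nope")
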