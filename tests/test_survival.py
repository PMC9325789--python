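import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from mmdep import (
    CohortTruth,
    bh_adjust,
    cox_fit,
    expression_groups,
    hr_for_power,
    km_logrank,
    meta_random_effects,
    power_two_group,
    run_survival_screen,
    simulate_cohort,
)


class TestExpressionGroups:
    def test_exact_quartiles_one_to_eight(self):
        expr = pd.Series(range(1, 9), index=[f"P{i}" for i in range(8)], dtype=float)
        grp = expression_groups(expr)
        assert set(expr[grp.low]) == {1.0, 2.0}
        assert set(expr[grp.high]) == {7.0, 8.0}

    def test_heavy_ties_go_to_extreme_group(self, caplog):
        vals = np.concatenate([np.zeros(6), np.arange(1, 15, dtype=float)])
        expr = pd.Series(vals, index=[f"P{i}" for i in range(20)])
        with caplog.at_level("WARNING", logger="mmdep"):
            grp = expression_groups(expr)
        assert (expr[grp.low] == 0).all() and len(grp.low) == 6
        assert any("tied" in r.message for r in caplog.records)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            expression_groups(pd.Series(np.arange(7.0)))

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="quartiles coincide"):
            expression_groups(pd.Series(np.ones(10)))


class TestKmLogrank:
    def test_identical_groups_null_statistic(self):
        times = pd.Series([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = pd.Series([1, 1, 0, 1, 1, 1, 0, 1])
        groups = pd.Series(["low"] * 4 + ["high"] * 4)
        _, _, stat, p = km_logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_enumerated_risk_sets(self):
        # group A events at {1, 2}, group B at {3, 4}: enumerate the four
        # risk sets and form the O-E / hypergeometric-variance statistic
        times = pd.Series([1.0, 2.0, 3.0, 4.0])
        events = pd.Series([1, 1, 1, 1])
        groups = pd.Series(["low", "low", "high", "high"])
        o_minus_e = var = 0.0
        for t in [1.0, 2.0, 3.0, 4.0]:
            at_risk = times >= t
            n = at_risk.sum()
            n_low = (at_risk & (groups == "low")).sum()
            d = ((times == t) & (events == 1)).sum()
            o = ((times == t) & (events == 1) & (groups == "low")).sum()
            o_minus_e += o - d * n_low / n
            if n > 1:
                var += d * (n_low / n) * (1 - n_low / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        _, _, stat, _ = km_logrank(times, events, groups)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_km_curves_non_increasing(self):
        cohort = simulate_cohort(200, ["G"], CohortTruth(), seed=2)
        grp = expression_groups(cohort.expression.loc["G"])
        keep = grp.labels.isin(["low", "high"])
        clin = cohort.clinical[keep]
        km_low, km_high, _, _ = km_logrank(
            clin["os_time"], clin["os_event"], grp.labels[keep]
        )
        for curve in (km_low, km_high):
            assert curve.iloc[:, 0].is_monotonic_decreasing

    def test_logrank_p_tracks_unadjusted_cox_wald_p(self):
        # sanity: the two tests of the same contrast agree to within an
        # order of magnitude on a moderately sized cohort
        truth = CohortTruth(log_hr={"G": 0.6})
        cohort = simulate_cohort(500, ["G"], truth, seed=14)
        grp = expression_groups(cohort.expression.loc["G"])
        keep = grp.labels.isin(["low", "high"])
        clin = cohort.clinical[keep]
        res = cox_fit(
            clin["os_time"], clin["os_event"],
            (grp.labels[keep] == "low").astype(int),
        )
        assert abs(np.log10(res.logrank_p) - np.log10(res.p)) <= 1.0

    def test_km_reaches_zero_after_last_event(self):
        times = pd.Series([1.0, 2.0, 3.0, 5.0])
        events = pd.Series([1, 1, 1, 1])
        groups = pd.Series(["low", "low", "high", "high"])
        km_low, km_high, _, _ = km_logrank(times, events, groups)
        assert km_low.iloc[-1, 0] == pytest.approx(0.0)
        assert km_high.iloc[-1, 0] == pytest.approx(0.0)


class TestCoxFit:
    def make_cohort(self, n=400, beta=0.0, seed=0):
        truth = CohortTruth(log_hr={"G": beta} if beta else {})
        cohort = simulate_cohort(n, ["G"], truth, seed=seed)
        grp = expression_groups(cohort.expression.loc["G"])
        keep = grp.labels.isin(["low", "high"])
        clin = cohort.clinical[keep]
        return clin, (grp.labels[keep] == "low").astype(int)

    def test_null_gene_ci_covers_one_most_seeds(self):
        covered = 0
        for seed in range(20):
            clin, ind = self.make_cohort(n=400, seed=seed)
            res = cox_fit(clin["os_time"], clin["os_event"], ind,
                          covariates=clin[["age", "sex", "iss"]])
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 17

    def test_single_group_rejected(self):
        clin, ind = self.make_cohort()
        with pytest.raises(ValueError, match="single expression group"):
            cox_fit(clin["os_time"], clin["os_event"], ind * 0 + 1)

    def test_too_few_events_rejected(self):
        clin, ind = self.make_cohort(n=400)
        events = clin["os_event"] * 0
        events.iloc[:5] = 1
        with pytest.raises(ValueError, match=">= 10 events"):
            cox_fit(clin["os_time"], events, ind)

    def test_singular_design_rejected(self):
        clin, ind = self.make_cohort()
        cov = clin[["age", "sex", "iss"]].copy()
        cov["age"] = 50.0  # constant column -> rank deficient
        with pytest.raises(ValueError, match="singular"):
            cox_fit(clin["os_time"], clin["os_event"], ind, covariates=cov)

    def test_missing_iss_dropped_and_counted(self):
        clin, ind = self.make_cohort(n=600)
        cov = clin[["age", "sex", "iss"]].copy()
        cov.iloc[:10, cov.columns.get_loc("iss")] = np.nan
        res = cox_fit(clin["os_time"], clin["os_event"], ind, covariates=cov)
        assert res.n_dropped_iss == 10
        assert res.n_low + res.n_high == len(clin) - 10

    def test_monotone_likelihood_flagged_not_crashed(self):
        # low group entirely event-free with shorter follow-up: the partial
        # likelihood is monotone and the Wald CI unbounded
        n = 40
        times = pd.Series(np.concatenate([np.full(n, 100.0), np.linspace(1, 50, n)]))
        events = pd.Series(np.concatenate([np.zeros(n, int), np.ones(n, int)]))
        ind = pd.Series(np.concatenate([np.ones(n, int), np.zeros(n, int)]))
        res = cox_fit(times, events, ind)
        assert res.flagged
        assert res.ci_high == np.inf

    def test_orientation_low_expression_adverse(self):
        # planted beta > 0 on the low quartile must yield HR > 1
        clin, ind = self.make_cohort(n=1500, beta=0.7, seed=3)
        res = cox_fit(clin["os_time"], clin["os_event"], ind,
                      covariates=clin[["age", "sex", "iss"]])
        assert res.hr > 1.3
        assert res.ci_low < res.hr < res.ci_high


class TestMetaRandomEffects:
    def test_hand_computed_two_cohort_case(self):
        res = meta_random_effects([0.0, 1.0], [1.0, 1.0])
        assert res.q_stat == pytest.approx(0.5, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.pooled_log_hr == pytest.approx(0.5, abs=1e-12)
        assert res.pooled_se == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_identical_cohorts_no_heterogeneity(self):
        res = meta_random_effects([0.3, 0.3], [0.2, 0.2])
        assert res.pooled_log_hr == pytest.approx(0.3)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0

    def test_single_cohort_passthrough(self):
        res = meta_random_effects([0.4], [0.1])
        assert res.pooled_log_hr == 0.4
        assert res.pooled_se == 0.1
        assert res.tau2 == 0.0 and np.isnan(res.q_stat)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_zero_tau2_reduces_to_fixed_effects(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 8)
        se = rng.uniform(0.1, 1.0, k)
        # draw effects close enough that Q <= k-1 forces tau2 = 0
        y = np.full(k, rng.normal()) + rng.normal(0, 0.001, k)
        res = meta_random_effects(y, se)
        w = 1 / se**2
        if res.tau2 == 0.0:
            assert res.pooled_log_hr == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)
            assert res.pooled_se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            meta_random_effects([0.1, 0.2], [0.5, 0.0])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agrees_with_metafor_reference(self):
        y = [0.41, -0.12, 0.78, 0.25]
        se = [0.20, 0.15, 0.35, 0.18]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({','.join(map(str, y))}), sei=c({','.join(map(str, se))}), method='DL');"
            "cat(jsonlite::toJSON(list(b=as.numeric(r$b), se=r$se, tau2=r$tau2, Q=r$QE), digits=I(14)))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        res = meta_random_effects(y, se)
        assert res.pooled_log_hr == pytest.approx(ref["b"][0], abs=1e-8)
        assert res.pooled_se == pytest.approx(ref["se"][0], abs=1e-8)
        assert res.tau2 == pytest.approx(ref["tau2"][0], abs=1e-8)
        assert res.q_stat == pytest.approx(ref["Q"][0], abs=1e-8)


class TestBhAdjust:
    def test_step_up_worked_example(self):
        q, reject = bh_adjust([0.01, 0.02, 0.03, 0.04], fdr=0.05)
        assert reject.all()  # largest p = 0.04 <= (4/4)*0.05

    def test_single_p_passthrough(self):
        q, _ = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_matches_step_up_brute_force(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, 37)
        q, _ = bh_adjust(p)
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            brute[i] = running
        assert np.allclose(q, brute, atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_order_invariance_and_bonferroni_superset(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-4, 1.0, 25)
        q, reject = bh_adjust(p, fdr=0.05)
        perm = rng.permutation(25)
        q_perm, _ = bh_adjust(p[perm])
        assert np.allclose(np.sort(q), np.sort(q_perm), atol=1e-15)
        bonferroni = p <= 0.05 / len(p)
        assert np.all(reject[bonferroni])

    def test_empty_input(self):
        q, reject = bh_adjust([])
        assert len(q) == 0 and len(reject) == 0


class TestPower:
    def test_null_hr_gives_alpha_over_two(self):
        assert power_two_group(100, 0.5, 1.0, 0.05) == pytest.approx(0.025, abs=1e-6)

    def test_worked_normal_cdf_case(self):
        expected = norm.cdf(np.log(2) * np.sqrt(100 * 0.25) - norm.ppf(0.975))
        assert power_two_group(100, 0.5, 2.0, 0.05) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.934, abs=0.001)

    def test_monotone_in_events(self):
        powers = [power_two_group(d, 0.5, 1.5) for d in (20, 50, 100, 300)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_hr_for_power_inverts(self):
        hr = hr_for_power(200, 0.5, 0.8)
        assert power_two_group(200, 0.5, hr) == pytest.approx(0.8, abs=1e-9)

    def test_invalid_hr_rejected(self):
        with pytest.raises(ValueError):
            power_two_group(100, 0.5, 0.0)


class TestRunSurvivalScreen:
    def test_single_cohort_meta_equals_cohort_fit(self):
        cohort = simulate_cohort(300, ["G1", "G2"], CohortTruth(), seed=6)
        meta, cox = run_survival_screen(["G1", "G2"], [cohort], endpoints=("os",))
        row = meta[meta.gene == "G1"].iloc[0]
        fit = cox[(cox.gene == "G1")].iloc[0]
        assert row["pooled_log_hr"] == pytest.approx(fit["log_hr"], abs=1e-12)
        assert row["pooled_se"] == pytest.approx(fit["se"], abs=1e-12)
        assert row["tau2"] == 0.0

    def test_gene_absent_from_one_cohort_pooled_over_rest(self):
        c1 = simulate_cohort(300, ["G1", "G2"], CohortTruth(), seed=7, name="c1")
        c2 = simulate_cohort(250, ["G1"], CohortTruth(), seed=8, name="c2")
        meta, cox = run_survival_screen(["G1", "G2"], [c1, c2], endpoints=("os",))
        assert meta.loc[meta.gene == "G2", "k_cohorts"].iloc[0] == 1
        assert meta.loc[meta.gene == "G1", "k_cohorts"].iloc[0] == 2

    def test_gene_absent_everywhere_rejected(self):
        cohort = simulate_cohort(300, ["G1"], CohortTruth(), seed=9)
        with pytest.raises(ValueError, match="absent from every cohort"):
            run_survival_screen(["GX"], [cohort], endpoints=("os",))

    def test_bh_family_is_per_endpoint(self):
        cohort = simulate_cohort(400, ["G1", "G2", "G3"], CohortTruth(), seed=10)
        meta, _ = run_survival_screen(["G1", "G2", "G3"], [cohort])
        for endpoint, sub in meta.groupby("endpoint"):
            q, _ = bh_adjust(sub["p_meta"].to_numpy())
            assert np.allclose(np.sort(sub["q_bh"]), np.sort(q), atol=1e-12)
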