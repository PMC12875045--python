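"""Cox screening, Kaplan-Meier, log-rank, rank-sum screen, regression,
and the gene-set bootstrap correlation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from conftest import cox_breslow_loglik_oracle, logrank_chi2_lifelines
from evmacro import clinical as cl
from evmacro import synthetic_data as sd


def _cohort(time, event, x):
    return pd.DataFrame({"time_months": time, "event": event, "X": x})


class TestCox:
    TINY = _cohort(
        time=[2.0, 4.0, 5.0, 7.0, 9.0, 12.0],
        event=[1, 1, 0, 1, 1, 1],
        x=[1.2, 0.8, -0.3, -0.9, 0.1, -1.5],
    )

    def test_tiny_fixture_matches_direct_partial_likelihood_maximum(self):
        fit = cl.cox_univariate(self.TINY, "X")
        t = self.TINY["time_months"].to_numpy()
        e = self.TINY["event"].to_numpy()
        x = self.TINY["X"].to_numpy()
        res = optimize.minimize_scalar(
            lambda b: -cox_breslow_loglik_oracle(b, t, e, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit["beta"] == pytest.approx(res.x, abs=1e-6)

    def test_agrees_with_lifelines_efron(self):
        from lifelines import CoxPHFitter

        coh = sd.simulate_cohort(150, {"X": 0.6}, censor_rate=0.2, seed=2)
        ours = cl.cox_univariate(coh, "X", ties="efron")
        cph = CoxPHFitter()
        cph.fit(coh[["time_months", "event", "X"]],
                duration_col="time_months", event_col="event")
        assert ours["beta"] == pytest.approx(cph.params_["X"], abs=1e-5)
        assert ours["se"] == pytest.approx(cph.standard_errors_["X"], abs=1e-4)

    def test_null_covariate_hr_near_one_within_ci(self):
        coh = sd.simulate_cohort(500, {"X": 0.0}, censor_rate=0.0, seed=3)
        fit = cl.cox_univariate(coh, "X")
        assert fit["ci_low"] < 1.0 < fit["ci_high"]

    def test_constant_covariate_and_no_events_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cl.cox_univariate(_cohort([1, 2, 3], [1, 1, 1], [5, 5, 5]), "X")
        with pytest.raises(ValueError, match="events"):
            cl.cox_univariate(_cohort([1, 2, 3], [0, 0, 1], [1, 2, 3]), "X")

    def test_scaling_equivariance(self):
        coh = sd.simulate_cohort(200, {"X": 0.7}, censor_rate=0.1, seed=4)
        fit1 = cl.cox_univariate(coh, "X")
        coh2 = coh.copy()
        coh2["X"] = coh2["X"] * 2.0
        fit2 = cl.cox_univariate(coh2, "X")
        assert fit2["beta"] == pytest.approx(fit1["beta"] / 2.0, rel=1e-6)

    def test_recovers_planted_hr_three(self):
        ok = 0
        for seed in range(50):
            coh = sd.simulate_cohort(400, {"X": np.log(3.0)},
                                     censor_rate=0.0, seed=seed)
            if 2.4 <= cl.cox_univariate(coh, "X")["HR"] <= 3.75:
                ok += 1
        assert ok >= 45


class TestLogrankKM:
    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 1, 1, 1, 1, 1, 1]
        group = [0, 0, 0, 0, 1, 1, 1, 1]
        res = cl.logrank(time, event, group)
        # groups share every event time, so observed = expected at each
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_statistic_matches_lifelines(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(10, 40)
        event = rng.random(40) < 0.8
        group = rng.integers(0, 2, 40)
        ours = cl.logrank_statistic(time, event.astype(int), group)
        theirs = logrank_chi2_lifelines(time, event.astype(int), group)
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_symmetric_under_label_swap_and_nonnegative(self):
        rng = np.random.default_rng(6)
        time = rng.exponential(10, 30)
        event = (rng.random(30) < 0.7).astype(int)
        group = rng.integers(0, 2, 30)
        a = cl.logrank_statistic(time, event, group)
        b = cl.logrank_statistic(time, event, 1 - group)
        assert a == pytest.approx(b) and a >= 0

    def test_exact_p_matches_brute_force_enumeration(self):
        # all events in one group at earlier times, no censoring, n = 8
        time = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        event = np.ones(8, dtype=int)
        group = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = cl.logrank(time, event, group, method="exact")
        from itertools import combinations

        obs = cl.logrank_statistic(time, event, group)
        hits = total = 0
        for idx in combinations(range(8), 4):
            lab = np.zeros(8, int)
            lab[list(idx)] = 1
            # independent statistic route for the oracle
            chi2 = logrank_chi2_lifelines(time, event, lab)
            total += 1
            hits += chi2 >= obs - 1e-9
        assert res["p"] == pytest.approx(hits / total, abs=1e-12)
        assert res["p"] == pytest.approx(2 / 70)  # the two extreme labelings

    def test_km_median_no_censoring_equals_sample_median(self):
        rng = np.random.default_rng(7)
        time = rng.exponential(20, 101)
        cur = cl.km_curve(time, np.ones(101, int))
        below = cur[cur["survival"] <= 0.5]
        assert below["time"].iloc[0] == pytest.approx(np.median(time))

    def test_km_curve_is_nonincreasing_from_one(self):
        rng = np.random.default_rng(8)
        time = rng.exponential(5, 60)
        event = (rng.random(60) < 0.7).astype(int)
        cur = cl.km_curve(time, event)
        s = cur["survival"].to_numpy()
        assert s[0] <= 1.0 + 1e-12 and (np.diff(s) <= 1e-12).all()

    def test_quantile_split_workflow(self):
        coh = sd.simulate_cohort(120, {"X": np.log(3.0)}, censor_rate=0.1, seed=9)
        res = cl.km_quantile_split(coh, "X", quantile=0.5)
        assert set(res["curves"]) == {"low", "high"}
        assert res["split_hr"] > 1.0  # high level, worse survival
        assert res["logrank_p"] < 0.05
        assert res["median_survival"]["high"] < res["median_survival"]["low"]

    def test_degenerate_split_rejected(self):
        coh = _cohort([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="degenerate"):
            cl.km_quantile_split(coh, "X", quantile=0.5)


class TestPlasmaScreen:
    def test_identical_distributions_p_one(self):
        case = pd.DataFrame({"p1": [1.0, 2.0, 3.0, 4.0]})
        control = pd.DataFrame({"p1": [1.0, 2.0, 3.0, 4.0]})
        res = cl.plasma_marker_screen(case, control)
        assert res.loc["p1", "p"] == pytest.approx(1.0)

    def test_exact_fixture_u_zero_p_point_one(self):
        case = pd.DataFrame({"p1": [1.0, 2.0, 3.0]})
        control = pd.DataFrame({"p1": [4.0, 5.0, 6.0]})
        res = cl.plasma_marker_screen(case, control)
        assert res.loc["p1", "U"] == 0
        assert res.loc["p1", "method"] == "exact"
        assert res.loc["p1", "p"] == pytest.approx(0.1, abs=1e-12)

    def test_all_tied_flagged(self):
        case = pd.DataFrame({"p1": [2.0, 2.0, 2.0]})
        control = pd.DataFrame({"p1": [2.0, 2.0, 2.0]})
        res = cl.plasma_marker_screen(case, control)
        assert res.loc["p1", "all_tied"] and res.loc["p1", "p"] == 1.0

    def test_exact_and_asymptotic_branches_agree(self):
        # the continuity-corrected normal approximation deviates from the
        # exact tail by up to ~0.016 at n = 6 + 6
        rng = np.random.default_rng(10)
        for _ in range(20):
            a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
            case = pd.DataFrame({"p1": a})
            control = pd.DataFrame({"p1": b})
            exact = cl.plasma_marker_screen(case, control, exact_max_n=12)
            approx = cl.plasma_marker_screen(case, control, exact_max_n=0)
            assert exact.loc["p1", "p"] == pytest.approx(
                approx.loc["p1", "p"], abs=0.02
            )


class TestRegression:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = cl.regress_paired_expression(x, x)
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_five_point_fixture_matches_t_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.1, 2.3, 2.8, 4.4, 4.9])
        fit = cl.regress_paired_expression(x, y)
        n = 5
        sxx = ((x - x.mean()) ** 2).sum()
        resid = y - fit["intercept"] - fit["slope"] * x
        se = np.sqrt((resid**2).sum() / (n - 2) / sxx)
        t = fit["slope"] / se
        assert fit["p"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2), abs=1e-10)

    def test_null_slope_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        ps = [
            cl.regress_paired_expression(rng.normal(size=20), rng.normal(size=20))["p"]
            for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").statistic < 1.63 / np.sqrt(500)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cl.regress_paired_expression([1, 1, 1], [1, 2, 3])


class TestBootstrapCorrelation:
    def test_whole_universe_marker_set_gives_p_one(self):
        x, y, _ = sd.simulate_paired_expression(50, 10, 0.5, seed=12)
        res = cl.bootstrap_geneset_correlation(x, y, list(x.index),
                                               n_boot=500, seed=0)
        assert res["p"] == pytest.approx(1.0)
        assert np.allclose(res["null_r"], res["r_observed"])

    def test_seeded_determinism(self):
        x, y, markers = sd.simulate_paired_expression(100, 20, 0.7, seed=13)
        r1 = cl.bootstrap_geneset_correlation(x, y, markers, n_boot=1000, seed=5)
        r2 = cl.bootstrap_geneset_correlation(x, y, markers, n_boot=1000, seed=5)
        np.testing.assert_array_equal(r1["null_r"], r2["null_r"])
        assert r1["p"] == r2["p"]

    def test_correlated_markers_get_small_p(self):
        x, y, markers = sd.simulate_paired_expression(400, 30, 0.9,
                                                      noise_sd=0.05, seed=14)
        res = cl.bootstrap_geneset_correlation(x, y, markers, n_boot=2000, seed=1)
        assert res["p"] < 0.01

    def test_p_on_grid_and_plus_one_variant(self):
        x, y, markers = sd.simulate_paired_expression(100, 10, 0.0, seed=15)
        res = cl.bootstrap_geneset_correlation(x, y, markers, n_boot=200, seed=2)
        assert res["p"] * 200 == pytest.approx(round(res["p"] * 200))
        plus = cl.bootstrap_geneset_correlation(x, y, markers, n_boot=200,
                                                seed=2, plus_one=True)
        assert plus["p"] == pytest.approx((res["hits"] + 1) / 201)

    def test_oversized_marker_set_rejected(self):
        x, y, _ = sd.simulate_paired_expression(20, 5, 0.5, seed=16)
        with pytest.raises(ValueError):
            cl.bootstrap_geneset_correlation(
                x, y, [f"M{i}" for i in range(25)], n_boot=10
            )
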