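"""Panel threshold regression: within transform, concentrated search,
bootstrap number test, LR sets, cluster-robust inference, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foodcarbon.synthetic import SyntheticConfig, generate_panel
from foodcarbon.threshold import (
    ThresholdModel,
    WithinDesign,
    cluster_robust_cov,
    concentrated_ssr,
    estimate_threshold,
    fit_report,
    format_report,
    lr_confidence_set,
    lr_critical_value,
    parse_report,
    threshold_number_test,
    within_transform,
)
from foodcarbon.threshold import _profile_ssr, _stars

TOY_MODEL = ThresholdModel(controls=("x",))


class TestWithinTransform:
    def test_pencil_and_paper_demeaning(self):
        # two households, two waves each: deviations from household means
        df = pd.DataFrame(
            {
                "household_id": [1, 1, 2, 2],
                "province_id": [0, 0, 1, 1],
                "wave": [2004, 2006, 2004, 2006],
                "hhinc": [1.0, 3.0, 2.0, 6.0],
                "x": [0.0, 2.0, 1.0, 1.0],
                "ghg": [1.0, 3.0, 2.0, 6.0],
            }
        )
        d = within_transform(df, TOY_MODEL)
        np.testing.assert_allclose(d.yt, [-1.0, 1.0, -2.0, 2.0])
        np.testing.assert_allclose(d.qt, [-1.0, 1.0, -2.0, 2.0])
        # x: household means 1 and 1 -> deviations [-1, 1, 0, 0]
        np.testing.assert_allclose(d.Wt[:, 0], [-1.0, 1.0, 0.0, 0.0])

    def test_household_means_are_zero(self, small_panel):
        d = within_transform(small_panel)
        for v in (d.yt, d.qt):
            means = np.bincount(d.codes, weights=v) / d.counts
            assert np.abs(means).max() < 1e-10

    def test_idempotent(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        np.testing.assert_allclose(d.demean(d.yt), d.yt, atol=1e-12)

    def test_constant_within_household_maps_to_zero(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        const = toy_panel.sort_values(["household_id", "wave"])[
            "household_id"].to_numpy(dtype=float)
        np.testing.assert_allclose(d.demean(const), 0.0, atol=1e-12)

    def test_time_invariant_control_dropped_with_warning(self, toy_panel):
        df = toy_panel.assign(fixed=toy_panel["household_id"] * 2.0)
        with pytest.warns(UserWarning, match="fixed"):
            d = within_transform(df, ThresholdModel(controls=("x", "fixed")))
        assert "fixed" not in d.W_names

    def test_single_wave_household_dropped(self, toy_panel):
        df = toy_panel.drop(index=[1])  # household 0 keeps one row
        with pytest.warns(UserWarning, match="single"):
            d = within_transform(df, TOY_MODEL)
        assert 0 not in d.households


def _brute_ssr(panel, gamma, controls=("x",)):
    """Independent oracle: explicit demeaning via pandas, dense lstsq."""
    df = panel.sort_values(["household_id", "wave"]).copy()
    df["x1"] = df["hhinc"] * (df["hhinc"] <= gamma)
    df["x2"] = df["hhinc"] * (df["hhinc"] > gamma)
    waves = sorted(df["wave"].unique())
    cols = ["ghg", "x1", "x2", *controls]
    for w in waves[1:]:
        df[f"w{w}"] = (df["wave"] == w).astype(float)
        cols.append(f"w{w}")
    dem = df.groupby("household_id")[cols].transform(lambda s: s - s.mean())
    y = dem["ghg"].to_numpy()
    X = dem.drop(columns="ghg").to_numpy()
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


class TestConcentratedSSR:
    def test_matches_brute_force_oracle(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        for gamma in np.quantile(toy_panel["hhinc"], [0.3, 0.5, 0.7]):
            assert concentrated_ssr(d, gamma=gamma) == pytest.approx(
                _brute_ssr(toy_panel, gamma), rel=1e-9
            )

    def test_profiled_grid_matches_direct_solves(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        grid = d.build_grid()
        ssr, _ = _profile_ssr(d, grid, d.yt[:, None], d.basis())
        direct = np.array([concentrated_ssr(d, gamma=g) for g in grid])
        np.testing.assert_allclose(ssr[:, 0], direct, rtol=1e-8)

    def test_empty_regime_is_infeasible(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        assert concentrated_ssr(d, gamma=toy_panel["hhinc"].min() - 1) == np.inf

    def test_noiseless_dgp_has_zero_ssr_at_truth(self):
        cfg = SyntheticConfig(
            n_households=100, sigma_eps=0.0, sigma_mu=0.5, seed=5,
            true_gamma=6.55,
        )
        panel = generate_panel(cfg)
        d = within_transform(panel)
        assert concentrated_ssr(d, gamma=cfg.true_gamma) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_step_function_between_observations(self, toy_panel):
        # S1 is constant between adjacent sorted incomes: evaluating at a
        # midpoint equals evaluating at the observation below it
        d = within_transform(toy_panel, TOY_MODEL)
        q = np.sort(toy_panel["hhinc"].unique())
        k = len(q) // 2
        mid = 0.5 * (q[k] + q[k + 1])
        assert concentrated_ssr(d, gamma=mid) == pytest.approx(
            concentrated_ssr(d, gamma=q[k]), rel=1e-12
        )


class TestEstimateThreshold:
    def test_exhaustive_search_equivalence(self, toy_panel):
        # grid-search result equals brute force over every distinct income
        d = within_transform(toy_panel, TOY_MODEL)
        fit = estimate_threshold(d)
        grid = d.build_grid()
        brute = [(g, _brute_ssr(toy_panel, g)) for g in grid]
        g_best = min(brute, key=lambda t: (t[1], t[0]))[0]
        assert fit.gamma_hat == pytest.approx(g_best)

    def test_recovers_true_threshold_low_noise(self, clean_config, clean_panel):
        fit = estimate_threshold(clean_panel)
        lo, hi = fit.confidence_set(0.05)
        assert lo <= clean_config.true_gamma <= hi
        assert abs(fit.gamma_hat - clean_config.true_gamma) < 0.25
        assert fit.beta_low == pytest.approx(clean_config.beta_low, rel=0.25)
        assert fit.beta_high == pytest.approx(clean_config.beta_high, rel=0.25)

    def test_argmin_and_lr_invariants(self, clean_panel):
        fit = estimate_threshold(clean_panel)
        curve = fit.lr_curve
        assert fit.ssr == pytest.approx(curve["ssr"].min())
        at_hat = curve.loc[curve["gamma"] == fit.gamma_hat, "lr"].iloc[0]
        assert at_hat == 0.0
        assert (curve["lr"] >= 0).all()
        lo, hi = fit.confidence_set()
        assert lo <= fit.gamma_hat <= hi

    def test_refit_ssr_matches_search_minimum(self, toy_panel):
        d = within_transform(toy_panel, TOY_MODEL)
        fit = estimate_threshold(d)
        assert fit.ssr == pytest.approx(
            concentrated_ssr(d, gamma=fit.gamma_hat), rel=1e-9
        )

    def test_no_feasible_grid_raises(self, toy_panel):
        with pytest.raises(RuntimeError, match="feasible"):
            estimate_threshold(toy_panel, TOY_MODEL, min_share=0.8)


class TestLRConfidenceSet:
    def test_critical_value_closed_form(self):
        assert lr_critical_value(0.05) == pytest.approx(7.3523, abs=1e-4)
        # direct evaluation of -2 ln(1 - sqrt(1 - alpha))
        assert lr_critical_value(0.10) == pytest.approx(
            -2 * np.log(1 - np.sqrt(0.90)), rel=1e-12
        )
        with pytest.raises(ValueError):
            lr_critical_value(1.5)

    def test_gamma_hat_always_inside(self, clean_panel):
        fit = estimate_threshold(clean_panel)
        for alpha in (0.01, 0.05, 0.20, 0.90):
            lo, hi = lr_confidence_set(fit, alpha)
            assert lo <= fit.gamma_hat <= hi

    def test_interval_shrinks_with_noise(self):
        widths = []
        for sd in (0.6, 0.05):
            w = []
            for seed in range(4):
                cfg = SyntheticConfig(
                    n_households=300, true_gamma=6.5, sigma_eps=sd, seed=seed
                )
                fit = estimate_threshold(generate_panel(cfg))
                lo, hi = fit.confidence_set()
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[1] < widths[0]


class TestNumberTest:
    def test_f_statistic_two_ways(self, toy_panel):
        # SSR-difference machinery vs direct restricted/unrestricted fits
        with pytest.warns(UserWarning, match="coarse"):
            test = threshold_number_test(toy_panel, TOY_MODEL, n_boot=20, seed=0,
                                         max_thresholds=1)
        stage = test.stages[0]
        d = within_transform(toy_panel, TOY_MODEL)
        # restricted: single slope
        Xr = np.column_stack([d.rt, d.Wt])
        er = d.yt - Xr @ np.linalg.lstsq(Xr, d.yt, rcond=None)[0]
        S0 = float(er @ er)
        S1 = _brute_ssr(toy_panel, stage["gamma"])
        k_m = Xr.shape[1] + 1
        dof = d.n - d.n_households - k_m
        F_direct = (S0 - S1) / (S1 / dof)
        assert stage["F"] == pytest.approx(F_direct, abs=1e-8)

    def test_noiseless_threshold_p_zero(self):
        cfg = SyntheticConfig(
            n_households=120, sigma_eps=0.0, sigma_mu=0.5, seed=2,
            true_gamma=6.55,
        )
        panel = generate_panel(cfg)
        test = threshold_number_test(panel, n_boot=50, seed=0, max_thresholds=1)
        assert test.p_value(1) == 0.0

    def test_strong_threshold_detected_weak_second_not(self, clean_panel):
        test = threshold_number_test(clean_panel, n_boot=99, seed=0,
                                     max_thresholds=2)
        assert test.p_value(1) <= 0.01
        assert test.p_value(2) > 0.10

    def test_province_wild_scheme_runs(self, clean_panel):
        test = threshold_number_test(clean_panel, n_boot=50, seed=0,
                                     max_thresholds=1, scheme="province")
        assert test.p_value(1) <= 0.05

    def test_household_blocks_require_balance(self, clean_panel):
        unbal = clean_panel.drop(index=[0])
        with pytest.raises(ValueError, match="balanced"):
            threshold_number_test(unbal, n_boot=50, seed=0, max_thresholds=1)

    def test_pvalues_in_unit_interval(self, clean_panel):
        test = threshold_number_test(clean_panel, n_boot=60, seed=3,
                                     max_thresholds=3)
        for s in test.stages:
            assert 0.0 <= s["p_value"] <= 1.0
            assert s["n_boot"] == 60


class TestClusterRobustCov:
    def test_hand_computed_two_cluster_toy(self):
        # pencil-and-paper sandwich: X = [1 x], clusters {1,2},{3,4}
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 3.0, 5.0])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = cluster_robust_cov(X, y - X @ beta, np.array([1, 1, 2, 2]))
        # meat: S1=(-.5+.5, 0)=0... recompute per-observation clusters below;
        # here the within-cluster sums cancel the residual pattern exactly:
        np.testing.assert_allclose(cov, np.zeros((2, 2)), atol=1e-12)

    def test_hand_computed_four_singleton_clusters(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 3.0, 5.0])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = cluster_robust_cov(X, y - X @ beta, np.array([1, 2, 3, 4]))
        # hand arithmetic: XtX_inv=[[.5,-.5],[-.5,1]], meat=[[2.5,2],[2,2]],
        # c = (4/3)*(3/2) = 2
        np.testing.assert_allclose(
            cov, [[0.25, -0.25], [-0.25, 1.25]], atol=1e-12
        )

    def test_singleton_clusters_match_hc1(self):
        # every observation its own cluster: the factor collapses to N/(N-k)
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n) * (1 + X[:, 1] ** 2)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        cov = cluster_robust_cov(X, y - X @ beta, np.arange(n))
        hc1 = sm.OLS(y, X).fit(cov_type="HC1").cov_params()
        np.testing.assert_allclose(cov, np.asarray(hc1), rtol=1e-10)

    def test_matches_statsmodels_cluster(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 90
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        cl = rng.integers(0, 8, n)
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=n) + 0.5 * cl
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        ours = cluster_robust_cov(X, y - X @ beta, cl)
        theirs = (
            sm.OLS(y, X)
            .fit(cov_type="cluster", cov_kwds={"groups": cl})
            .cov_params()
        )
        np.testing.assert_allclose(ours, np.asarray(theirs), rtol=1e-10)

    def test_iid_close_to_classical(self):
        # homoskedastic i.i.d. errors: cluster-robust and classical SEs agree
        # on average over replicates
        rng = np.random.default_rng(3)
        ratios = []
        for _ in range(100):
            n = 200
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            cl = np.repeat(np.arange(20), 10)
            y = X @ [1.0, 1.0] + rng.normal(size=n)
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            e = y - X @ beta
            robust = np.sqrt(cluster_robust_cov(X, e, cl)[1, 1])
            classical = np.sqrt(
                (e @ e) / (n - 2) * np.linalg.inv(X.T @ X)[1, 1]
            )
            ratios.append(robust / classical)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_single_cluster_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="cluster"):
            cluster_robust_cov(X, np.ones(5), np.zeros(5))


class TestReporting:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.005, "***"), (0.04, "**"), (0.09, "*"), (0.2, "")],
    )
    def test_star_rule(self, p, expected):
        assert _stars(p) == expected

    def test_report_round_trips_through_csv(self, clean_panel):
        fit = estimate_threshold(clean_panel)
        test = threshold_number_test(clean_panel, n_boot=60, seed=0,
                                     max_thresholds=1)
        table = fit_report(fit, test)
        back = parse_report(table.to_csv(index=False))
        merged = table.merge(back, on="variable", suffixes=("", "_rt"))
        np.testing.assert_allclose(
            merged["coefficient"], merged["coefficient_rt"], rtol=1e-12
        )
        n_row = table.set_index("variable").loc["N", "coefficient"]
        assert n_row == fit.n_obs == len(clean_panel)

    def test_text_report_contains_key_numbers(self, clean_panel):
        fit = estimate_threshold(clean_panel)
        text = format_report(fit)
        assert f"{fit.gamma_hat:.4f}" in text
        assert "p<0.05" in text
        assert str(fit.n_obs) in text
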