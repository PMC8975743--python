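"""Proportional-odds, logistic and random-intercept fitters; 2x2 helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from pgxresponse.cohort import CohortConfig, generate_cohort
from pgxresponse.models import (
    _clm_nll_grad_hess,
    bin_side_effect_count,
    bonferroni_threshold,
    crude_or,
    fit_cumulative_logit,
    fit_logistic,
    fit_random_intercept,
    mixed_marginal_loglik,
    run_primary_analysis,
)

# --- fixed n=30 ordinal fixture with a binary group indicator -------------
FIXTURE_Y = np.array(
    [1, 2, 3, 1, 2, 2, 3, 1, 1, 2, 3, 3, 2, 1, 2, 3, 1, 2, 2, 1,
     3, 2, 1, 3, 3, 2, 2, 1, 3, 2]
)
FIXTURE_G = np.array(
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1,
     1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
)
# ML solution from an independent zooming dense-grid search over
# (theta1, theta2, beta), 12 refinement rounds of a 21^3 lattice:
GRID_THETA1 = -0.6931472
GRID_THETA2 = 1.0116009
GRID_BETA = 0.3184537
GRID_LOGLIK = -32.5556584


def _simulate_ordinal(rng, n, beta, thresholds=(-0.5, 1.0)):
    x = rng.normal(size=(n, len(np.atleast_1d(beta))))
    eta = x @ np.atleast_1d(beta)
    c1 = expit(thresholds[0] - eta)
    c2 = expit(thresholds[1] - eta)
    r = rng.random(n)
    y = np.where(r < c1, 1, np.where(r < c2, 2, 3))
    return y, x


class TestCumulativeLogit:
    def test_matches_grid_search_oracle(self):
        fit = fit_cumulative_logit(
            FIXTURE_Y, FIXTURE_G.reshape(-1, 1).astype(float), ["group"]
        )
        assert fit.converged
        assert fit.params["theta_1"] == pytest.approx(GRID_THETA1, abs=1e-4)
        assert fit.params["theta_2"] == pytest.approx(GRID_THETA2, abs=1e-4)
        assert fit.params["group"] == pytest.approx(GRID_BETA, abs=1e-4)
        assert fit.loglik == pytest.approx(GRID_LOGLIK, abs=1e-4)

    def test_matches_statsmodels(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        y, x = _simulate_ordinal(rng, 800, [0.5, -0.3])
        fit = fit_cumulative_logit(y, x, ["a", "b"])
        sm_fit = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.params["a"] == pytest.approx(sm_fit.params[0], abs=1e-4)
        assert fit.params["b"] == pytest.approx(sm_fit.params[1], abs=1e-4)

    def test_analytic_derivatives_match_finite_differences(self, rng):
        y, x = _simulate_ordinal(rng, 120, [0.4])
        params = np.array([-0.4, 0.9, 0.25])
        nll, grad, hess = _clm_nll_grad_hess(params, y, x, 3)
        eps = 1e-6
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            f_hi, _, _ = _clm_nll_grad_hess(params + e, y, x, 3, want_hess=False)
            f_lo, _, _ = _clm_nll_grad_hess(params - e, y, x, 3, want_hess=False)
            assert grad[i] == pytest.approx((f_hi - f_lo) / (2 * eps), rel=1e-5)
            _, g_hi, _ = _clm_nll_grad_hess(params + e, y, x, 3, want_hess=False)
            _, g_lo, _ = _clm_nll_grad_hess(params - e, y, x, 3, want_hess=False)
            np.testing.assert_allclose(
                hess[:, i], (g_hi - g_lo) / (2 * eps), rtol=1e-5, atol=1e-8
            )

    def test_parameter_recovery(self, rng):
        y, x = _simulate_ordinal(rng, 5000, [0.5])
        fit = fit_cumulative_logit(y, x)
        assert abs(fit.params["x1"] - 0.5) < 3 * fit.se["x1"]

    def test_null_effect_estimates_near_zero(self, rng):
        y, x = _simulate_ordinal(rng, 4000, [0.0])
        fit = fit_cumulative_logit(y, x)
        assert abs(fit.params["x1"]) < 3 * fit.se["x1"]

    def test_binary_collapse_equals_logistic(self, rng):
        """A 2-level cumulative-logit fit is the logistic fit of the collapsed
        outcome (theta1 = -intercept, shared slope)."""
        y, x = _simulate_ordinal(rng, 600, [0.6])
        z = (y >= 2).astype(int) + 1  # collapse to 2 ordinal levels
        clm = fit_cumulative_logit(z, x)
        logi = fit_logistic((y >= 2).astype(float), np.column_stack([np.ones(600), x]))
        assert clm.params["x1"] == pytest.approx(logi.params["x2"], abs=1e-6)
        assert clm.params["theta_1"] == pytest.approx(-logi.params["x1"], abs=1e-6)

    def test_single_level_outcome_flagged(self):
        fit = fit_cumulative_logit(np.ones(20, int), np.ones((20, 1)))
        assert not fit.converged
        assert "level" in fit.message

    def test_rank_deficient_design_rejected(self):
        x = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            fit_cumulative_logit(FIXTURE_Y, x)


class TestLogistic:
    def test_saturated_two_by_two_matches_crude_or(self):
        """Group-only logistic on the printed discontinuation counts equals
        the crude OR of the 2x2 table (0.60)."""
        y = np.concatenate([np.ones(32), np.zeros(63), np.ones(775), np.zeros(917)])
        g = np.concatenate([np.ones(95), np.zeros(1692)])
        fit = fit_logistic(y, np.column_stack([np.ones_like(g), g]), ["const", "poor"])
        c = fit.contrast("poor")
        assert c["or"] == pytest.approx(0.60, abs=0.005)
        assert c["or"] == pytest.approx(crude_or(32, 63, 775, 917).odds_ratio, rel=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(size=(500, 2))
        y = (rng.random(500) < expit(0.2 + x @ [0.8, -0.4])).astype(float)
        X = np.column_stack([np.ones(500), x])
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=False)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), ref.bse, atol=1e-5)

    def test_constant_outcome_flagged_not_raised(self):
        fit = fit_logistic(np.zeros(50), np.ones((50, 1)))
        assert not fit.converged
        assert "non-identifiable" in fit.message

    def test_beta_recovery_from_generator(self):
        """Generator round-trip: logistic refit recovers the simulated effect."""
        beta = np.log(1.6)
        cfg = CohortConfig(
            n_participants=6000,
            random_intercept_sd=0.0,
            n_drugs_dist=(1.0, 0.0, 0.0),
            drug_marginals={"sertraline": 1.0, "citalopram": 1e-12, "escitalopram": 1e-12},
            status_betas={"discontinued": {"poor": beta}},
        )
        rec = generate_cohort(cfg, seed=21).records
        X = np.column_stack(
            [
                np.ones(len(rec)),
                (rec["status"] == "poor").to_numpy(float),
                rec["age"].to_numpy(),
                rec["sex"].to_numpy(float),
            ]
        )
        fit = fit_logistic(rec["discontinued"].to_numpy(float), X,
                           ["const", "poor", "age", "sex"])
        assert abs(fit.params["poor"] - beta) < 3 * fit.se["poor"]


@pytest.fixture(scope="module")
def mixed_fixture():
    rng = np.random.default_rng(5)
    n = 400
    groups = np.repeat(np.arange(n), 2)
    u = rng.normal(0, 1.0, n)
    x = rng.normal(size=2 * n)
    eta = 0.3 + 0.5 * x + u[groups]
    y = (rng.random(2 * n) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(2 * n), x])
    return y, X, groups


class TestRandomIntercept:
    def test_sigma_zero_data_matches_fixed_fit(self):
        rng = np.random.default_rng(44)
        n = 1500
        groups = np.repeat(np.arange(n // 2), 2)[:n]
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.2 + 0.5 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        mixed = fit_random_intercept("logistic", y, X, groups)
        fixed = fit_logistic(y, X)
        np.testing.assert_allclose(
            mixed.params.to_numpy(), fixed.params.to_numpy(), atol=1e-3
        )

    def test_quadrature_matches_trapezoid_oracle(self):
        """AGH marginal likelihood vs direct fine-grid integration on a
        5-participant x 2-record fixture."""
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(5), 2)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = rng.integers(0, 2, size=10).astype(float)
        params = np.array([0.2, 0.5])
        sigma = 0.8
        agh = mixed_marginal_loglik("logistic", params, sigma, y, X, groups)
        us = np.linspace(-8 * sigma, 8 * sigma, 20001)
        total = 0.0
        for g in range(5):
            idx = groups == g
            eta = (X[idx] @ params)[:, None] + us[None, :]
            ll = (y[idx][:, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
            dens = np.exp(ll - us**2 / (2 * sigma**2)) / (sigma * np.sqrt(2 * np.pi))
            total += np.log(np.trapezoid(dens, us))
        assert agh == pytest.approx(total, abs=1e-5)

    def test_node_doubling_stability(self, mixed_fixture):
        """Fixed effects move by < 1e-4 when nodes go 15 -> 31."""
        y, X, groups = mixed_fixture
        f15 = fit_random_intercept("logistic", y, X, groups, n_nodes=15)
        f31 = fit_random_intercept("logistic", y, X, groups, n_nodes=31)
        np.testing.assert_allclose(
            f15.params.to_numpy(), f31.params.to_numpy(), atol=1e-4
        )

    def test_sigma_recovery(self):
        rng = np.random.default_rng(8)
        n = 3000
        groups = np.repeat(np.arange(n), 2)
        u = rng.normal(0, 1.0, n)
        x = rng.normal(size=2 * n)
        y = (rng.random(2 * n) < expit(0.2 + 0.5 * x + u[groups])).astype(float)
        X = np.column_stack([np.ones(2 * n), x])
        fit = fit_random_intercept("logistic", y, X, groups, names=["const", "x"])
        assert fit.converged
        assert abs(fit.sigma - 1.0) < 3 * fit.sigma_se
        assert abs(fit.params["x"] - 0.5) < 3 * fit.se["x"]

    def test_single_record_clusters_reduce_to_fixed(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(x)).astype(float)
        X = np.column_stack([np.ones(200), x])
        fit = fit_random_intercept("logistic", y, X, np.arange(200))
        assert fit.sigma == 0.0
        assert "degenerate" in fit.method

    def test_ordinal_mixed_recovers_effect(self):
        """Pooled-style mixed CLM recovers a simulated efficacy effect."""
        beta = np.log(1.41)
        cfg = CohortConfig(
            n_participants=4000,
            random_intercept_sd=1.0,
            status_betas={"efficacy": {"poor": beta}},
        )
        rec = generate_cohort(cfg, seed=31).records
        X = np.column_stack(
            [
                (rec["status"] == s).to_numpy(float)
                for s in ("poor", "intermediate", "rapid", "ultrarapid")
            ]
            + [rec["age"].to_numpy(), rec["sex"].to_numpy(float)]
            + [(rec["drug"] == d).to_numpy(float) for d in ("citalopram", "escitalopram")]
        )
        names = ["poor", "intermediate", "rapid", "ultrarapid", "age", "sex",
                 "drug_citalopram", "drug_escitalopram"]
        fit = fit_random_intercept(
            "clm", rec["efficacy"].to_numpy(int), X,
            rec["participant_id"].to_numpy(), names=names,
        )
        c = fit.contrast("poor")
        assert c["ci_low"] < np.exp(beta) < c["ci_high"]
        assert abs(fit.sigma - 1.0) < 4 * fit.sigma_se


class TestContingency:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((32, 63, 775, 917), 0.60),
            ((291, 562, 493, 791), 0.83),
            ((10, 10, 10, 10), 1.0),
        ],
    )
    def test_worked_examples(self, table, expected):
        assert crude_or(*table).odds_ratio == pytest.approx(expected, abs=0.005)

    def test_zero_cell_correction_flagged(self):
        result = crude_or(0, 10, 5, 5)
        assert result.corrected
        assert np.isfinite(result.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            crude_or(-1, 2, 3, 4)

    @settings(max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
    def test_reciprocal_identity(self, table):
        a, b, c, d = table
        assert crude_or(a, b, c, d).odds_ratio * crude_or(b, a, d, c).odds_ratio == (
            pytest.approx(1.0, rel=1e-9)
        )

    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 4, 0.0125), (0.05, 300, 0.05 / 300), (0.05, 1, 0.05)],
    )
    def test_bonferroni(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_bonferroni_rejects_bad_input(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)


class TestPrimaryAnalysis:
    def test_binning(self):
        np.testing.assert_array_equal(
            bin_side_effect_count([0, 1, 2, 3, 7]), [1, 2, 2, 3, 3]
        )

    def test_result_shape(self, small_cohort):
        results = run_primary_analysis(
            small_cohort.records, include_side_effect_scan=False
        )
        main = results[results["outcome"].isin(
            ["efficacy", "discontinued", "any_side_effect"])]
        # 3 outcomes x 4 scopes (3 drugs + pooled) x 4 contrasts
        assert len(main) == 3 * 4 * 4
        assert set(main["contrast"]) == {"poor", "intermediate", "rapid", "ultrarapid"}
        eff = results[results["family"] == "efficacy"]
        assert (eff["threshold"] == 0.0125).all()
        scan_thr = results[results["family"] == "side_effects"]["threshold"]
        assert np.allclose(scan_thr, 0.05 / 300)

    def test_side_effect_scan_family_size(self, small_cohort):
        results = run_primary_analysis(small_cohort.records, include_pooled=False)
        scan = results[results["family"] == "side_effects"]
        # (any + binned count + 23 specific) x 3 drugs x 4 contrasts = 300
        assert len(scan) == 300

    def test_missing_columns_named(self, small_cohort):
        with pytest.raises(ValueError, match="status"):
            run_primary_analysis(small_cohort.records.drop(columns=["status"]))

    def test_single_drug_pooled_equals_per_drug(self):
        cfg = CohortConfig(
            n_participants=500,
            n_drugs_dist=(1.0, 0.0, 0.0),
            drug_marginals={"sertraline": 1.0, "citalopram": 1e-12, "escitalopram": 1e-12},
            random_intercept_sd=0.0,
        )
        rec = generate_cohort(cfg, seed=3).records
        results = run_primary_analysis(rec, include_side_effect_scan=False)
        eff = results[results["outcome"] == "efficacy"]
        for contrast in ("poor", "intermediate"):
            per = eff[(eff["scope"] == "sertraline") & (eff["contrast"] == contrast)]
            pool = eff[(eff["scope"] == "pooled") & (eff["contrast"] == contrast)]
            if np.isfinite(per["beta"].iloc[0]):
                assert per["beta"].iloc[0] == pytest.approx(
                    pool["beta"].iloc[0], abs=1e-3
                )

    def test_wald_p_uniform_under_null(self):
        """Two-group CLM p-values are uniform under the null (KS check)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(300):
            y, x = _simulate_ordinal(rng, 300, [0.0])
            fit = fit_cumulative_logit(y, x)
            pvals.append(fit.contrast("x1")["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01
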