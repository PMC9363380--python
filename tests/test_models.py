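import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dietrenal.cohort import apply_exclusions
from dietrenal.errors import ConfigurationError, EstimationError, SeparationError
from dietrenal.models import (
    ModelSpec,
    build_design,
    fit_linear_change,
    fit_logistic_decline,
    interaction_lrt,
    item_removal_analysis,
    pct_change_vs_full,
    rescale_beta,
    rescale_or,
    trend_test,
)
from dietrenal.pipeline import build_analysis_frame
from dietrenal.simulate import GeneratorConfig, generate_cohort


def make_frame(n=1500, seed=0, **cfg):
    cohort = generate_cohort(GeneratorConfig(n_participants=n, n_centers=8, seed=seed, **cfg))
    analytic, _ = apply_exclusions(cohort.table)
    return build_analysis_frame(analytic)


@pytest.fixture(scope="module")
def frame():
    return make_frame(n=1500, seed=13)


# ---------------------------------------------------------------------------
# rescaling arithmetic


def test_beta_rescaling_by_16_17():
    assert rescale_beta(0.17) == pytest.approx(0.16, abs=1e-12)


def test_or_rescaling_on_log_scale():
    assert rescale_or(0.95) == pytest.approx(np.exp(np.log(0.95) * 16 / 17), rel=1e-12)


def test_percent_change_formula_matches_published_example():
    # full-score 0.23 vs 0.20 after removing an item: -13.04 %
    assert pct_change_vs_full(0.20, 0.23) == pytest.approx(-13.04, abs=0.01)
    # odds ratios compare on the log scale: 0.96 vs full 0.95 is ~ -20 %
    assert pct_change_vs_full(0.96, 0.95, scale="or") == pytest.approx(-20.4, abs=0.5)


# ---------------------------------------------------------------------------
# design construction


def test_nested_covariate_tiers(frame):
    cols = {}
    for tier in ("M1", "M2", "M3"):
        spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier=tier)
        _, X, _ = build_design(frame, spec)
        cols[tier] = set(X.columns)
    assert cols["M1"] < cols["M2"] < cols["M3"]
    assert "egfr_baseline" in cols["M1"]  # linear models adjust for baseline eGFR
    spec_log = ModelSpec(outcome="decline", score="ermed17", tier="M1")
    _, X_log, _ = build_design(frame, spec_log)
    assert "egfr_baseline" not in X_log.columns


def test_constant_covariate_is_estimation_error_naming_column(frame):
    bad = frame.copy()
    bad["bmi"] = 30.0
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M2")
    with pytest.raises(EstimationError, match="bmi"):
        build_design(bad, spec)


def test_single_cluster_is_an_error(frame):
    solo = frame.copy()
    solo["center"] = 0
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    with pytest.raises(EstimationError, match="cluster"):
        fit_linear_change(solo, spec)


# ---------------------------------------------------------------------------
# linear model


def test_reference_category_is_zero_and_cis_bracket_estimates(frame):
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    res = fit_linear_change(frame, spec)
    assert res.estimates["DecrMaint"] == (0.0, 0.0, 0.0)
    for est, lo, hi in res.estimates.values():
        assert lo <= est <= hi
    assert sum(res.n_per_category.values()) == len(frame)


def test_known_effect_recovered_within_monte_carlo_ci():
    estimates = []
    for seed in range(20):
        f = make_frame(n=1200, seed=100 + seed, true_effect_beta=0.8)
        spec = ModelSpec(outcome="delta_egfr", score="ermed17", coding="continuous", tier="M1")
        estimates.append(fit_linear_change(f, spec).continuous_estimate[0])
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - 0.8) < 1.96 * mc_se


def test_residuals_orthogonal_to_covariates(frame):
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M2")
    y, X, groups = build_design(frame, spec)
    res = sm.OLS(y, X).fit()
    products = X.to_numpy().T @ res.resid.to_numpy()
    assert np.max(np.abs(products)) / len(y) < 1e-8


def test_singleton_clusters_reduce_to_heteroskedasticity_robust_ses(frame):
    solo = frame.copy()
    solo["center"] = np.arange(len(solo))
    spec = ModelSpec(
        outcome="delta_egfr", score="ermed17", tier="M1", small_sample_correction=False
    )
    y, X, groups = build_design(solo, spec)
    cluster = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": np.asarray(groups), "use_correction": False}
    )
    hc0 = sm.OLS(y, X).fit(cov_type="HC0")
    np.testing.assert_allclose(cluster.bse.to_numpy(), hc0.bse.to_numpy(), rtol=1e-8)


def test_cluster_robust_ses_exceed_naive_under_intra_center_correlation():
    ratios = []
    for seed in range(10):
        cohort = generate_cohort(
            GeneratorConfig(
                n_participants=900, n_centers=30, seed=300 + seed, intra_center_icc=0.15
            )
        )
        analytic, _ = apply_exclusions(cohort.table)
        f = build_analysis_frame(analytic)
        spec = ModelSpec(outcome="delta_egfr", score="ermed17", coding="continuous", tier="M1")
        y, X, groups = build_design(f, spec)
        robust = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": np.asarray(groups)}
        )
        naive = sm.OLS(y, X).fit()
        ratios.append(robust.bse["per_point"] / naive.bse["per_point"])
    # center random intercepts in the residual inflate the sandwich SE
    assert np.mean(ratios) > 1.0


# ---------------------------------------------------------------------------
# logistic model


def test_odds_ratio_matches_cross_product_oracle():
    # with no covariates beyond the intercept and a binary exposure, the
    # fitted OR equals the contingency-table cross-product ratio
    rng = np.random.default_rng(17)
    n = 2000
    x = rng.random(n) < 0.4
    p = np.where(x, 0.25, 0.15)
    y = rng.random(n) < p
    X = pd.DataFrame({"const": 1.0, "x": x.astype(float)})
    res = sm.Logit(pd.Series(y.astype(float)), X).fit(disp=0)
    a = np.sum(x & y)
    b = np.sum(x & ~y)
    c = np.sum(~x & y)
    d = np.sum(~x & ~y)
    oracle = (a * d) / (b * c)
    assert np.exp(res.params["x"]) == pytest.approx(oracle, rel=1e-6)


def test_null_simulation_odds_ratios_center_on_one():
    ors = []
    for seed in range(15):
        f = make_frame(n=900, seed=500 + seed, true_effect_beta=0.0)
        spec = ModelSpec(outcome="decline", score="ermed17", coding="continuous", tier="M1")
        ors.append(np.log(fit_logistic_decline(f, spec).continuous_estimate[0]))
    mc_se = np.std(ors, ddof=1) / np.sqrt(len(ors))
    assert abs(np.mean(ors)) < 3 * mc_se


def test_known_log_odds_effect_recovered():
    # plant a strong protective effect and check the sign and magnitude range
    estimates = []
    for seed in range(10):
        f = make_frame(n=1500, seed=700 + seed, true_effect_beta=1.2)
        spec = ModelSpec(outcome="decline", score="ermed17", coding="continuous", tier="M1")
        estimates.append(np.log(fit_logistic_decline(f, spec).continuous_estimate[0]))
    assert np.mean(estimates) < -0.05  # higher adherence change protects


def test_zero_event_category_raises_separation_error(frame):
    broken = frame.copy()
    broken.loc[broken["ermed17_category"] == "T3", "decline"] = False
    spec = ModelSpec(outcome="decline", score="ermed17", tier="M1")
    with pytest.raises(SeparationError, match="T3"):
        fit_logistic_decline(broken, spec)


# ---------------------------------------------------------------------------
# trend and interaction


def test_trend_regressor_is_exactly_the_category_medians(frame):
    medians = frame.groupby("ermed17_category")["ermed17_delta"].median()
    coded = frame["ermed17_category_median"]
    for cat, med in medians.items():
        assert (coded[frame["ermed17_category"] == cat] == med).all()
    assert coded.nunique() == 4


def test_strong_effect_gives_tiny_trend_p():
    f = make_frame(n=4000, seed=900, true_effect_beta=1.5)
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    assert trend_test(f, spec) < 1e-3


def test_degenerate_medians_raise(frame):
    bad = frame.copy()
    bad["ermed17_category_median"] = 1.0
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    with pytest.raises(ConfigurationError, match="median"):
        trend_test(bad, spec)


def test_interaction_df_equals_number_of_cross_products(frame):
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    _, df, _ = interaction_lrt(frame, spec, "diabetes")
    assert df == 3  # three non-reference exposure categories x binary modifier
    cont = ModelSpec(outcome="delta_egfr", score="ermed17", coding="continuous", tier="M1")
    _, df_cont, _ = interaction_lrt(frame, cont, "diabetes")
    assert df_cont == 1


def test_single_level_modifier_is_an_error(frame):
    solo = frame.copy()
    solo["diabetes"] = True
    spec = ModelSpec(outcome="delta_egfr", score="ermed17", tier="M1")
    with pytest.raises(ConfigurationError, match="level"):
        interaction_lrt(solo, spec, "diabetes")


def test_null_interaction_statistic_follows_chi_square():
    from scipy import stats

    lrts = []
    for seed in range(40):
        f = make_frame(n=500, seed=1100 + seed, true_effect_beta=0.0)
        spec = ModelSpec(outcome="delta_egfr", score="ermed17", coding="continuous", tier="M1")
        stat, df, _ = interaction_lrt(f, spec, "intervention")
        assert df == 1
        lrts.append(stat)
    ks = stats.kstest(lrts, stats.chi2(1).cdf)
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# item removal


def test_item_removal_sum_identity(frame):
    for item in (1, 9, 17):
        d17 = frame["ermed17_delta"]
        d_item = frame[f"ermed_item_{item}_year1"].astype(float) - frame[
            f"ermed_item_{item}_baseline"
        ].astype(float)
        d16 = d17 - d_item
        assert ((d16 + d_item) == d17).all()


def test_item_removal_returns_17_rescaled_results(frame):
    results, full_lin, full_log = item_removal_analysis(frame)
    assert [r.item for r in results] == list(range(1, 18))
    for r in results:
        assert r.or_ci[0] <= r.rescaled_or <= r.or_ci[1]
        assert r.beta_ci[0] <= r.rescaled_beta <= r.beta_ci[1]
    assert full_lin.continuous_estimate is not None


def test_removing_constant_item_reproduces_full_fit_up_to_scaling(frame):
    work = frame.copy()
    # force item 5 constant at both timepoints: the 16-item change equals the
    # 17-item change and the refit must match the full fit exactly
    work["ermed_item_5_baseline"] = 1
    work["ermed_item_5_year1"] = 1
    work["ermed17_baseline"] = (
        sum(work[f"ermed_item_{i}_baseline"].astype(int) for i in range(1, 18))
    )
    work["ermed17_year1"] = (
        sum(work[f"ermed_item_{i}_year1"].astype(int) for i in range(1, 18))
    )
    work["ermed17_delta"] = work["ermed17_year1"] - work["ermed17_baseline"]
    results, full_lin, _ = item_removal_analysis(work)
    r5 = results[4]
    assert r5.rescaled_beta == pytest.approx(
        rescale_beta(full_lin.continuous_estimate[0]), rel=1e-9
    )
    assert r5.pct_change_beta == pytest.approx(
        pct_change_vs_full(rescale_beta(full_lin.continuous_estimate[0]), full_lin.continuous_estimate[0]),
        abs=1e-9,
    )
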