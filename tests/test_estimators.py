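"""Estimator correctness: hand-enumerated examples, algebraic identities,
and cross-checks against independently implemented fits."""

import numpy as np
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from hypothesis import given
from hypothesis import strategies as st

from crt_estimands import (
    CRTDataset,
    EstimatorError,
    FitOptions,
    cluster_robust_covariance,
    fit_cluster_level,
    fit_gee_exchangeable,
    fit_iee,
    fit_mixed_random_intercept,
    generate_dataset,
    preset_scenarios,
    summarize_clusters,
)

from conftest import random_dataset


@pytest.fixture(scope="module")
def figure1_replicate() -> CRTDataset:
    return generate_dataset(preset_scenarios("figure1"), replicate=0)


class TestIEE:
    def test_unweighted_is_difference_of_participant_means(self, toy_dataset):
        assert fit_iee(toy_dataset).estimate == pytest.approx(1.0, abs=1e-12)

    def test_inverse_size_weights_give_cluster_mean_contrast(self, toy_dataset):
        res = fit_iee(toy_dataset, weights="inverse_cluster_size")
        assert res.estimate == pytest.approx(1.5, abs=1e-12)
        assert res.estimand_target == "cluster_average"

    def test_constant_outcome_gives_zero_estimate_and_se(self, toy_dataset):
        d = CRTDataset(toy_dataset.cluster, toy_dataset.arm,
                       np.full(toy_dataset.n_participants, 4.2))
        res = fit_iee(d)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)
        assert res.se == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_with_cluster_robust_se(self, figure1_replicate):
        df = figure1_replicate.to_frame()
        ref = smf.ols("outcome ~ arm", df).fit(
            cov_type="cluster", cov_kwds={"groups": df["cluster_id"]}
        )
        res = fit_iee(figure1_replicate, opts=FitOptions(variance_correction="CR1"))
        assert res.estimate == pytest.approx(ref.params["arm"], abs=1e-10)
        # reference applies an extra (N-1)/(N-p) factor on top of G/(G-1)
        assert res.se == pytest.approx(ref.bse["arm"], rel=1e-3)

    def test_binomial_links_recover_saturated_contrasts(self, rng):
        # intercept + arm is saturated for a two-arm design, so each link's
        # coefficient equals the hand-computed contrast of raw arm rates
        g = 20
        sizes = rng.integers(5, 40, size=g)
        arms = np.repeat([0, 1], g // 2)
        cl = np.repeat([f"g{i}" for i in range(g)], sizes)
        arm = np.repeat(arms, sizes)
        p = np.where(arm == 1, 0.35, 0.55)
        y = (rng.random(sizes.sum()) < p).astype(float)
        d = CRTDataset(cl, arm, y)
        p1, p0 = y[arm == 1].mean(), y[arm == 0].mean()
        expected = {
            "logit": np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0)),
            "log": np.log(p1 / p0),
            "identity": p1 - p0,
        }
        for link, val in expected.items():
            res = fit_iee(d, family="binomial", link=link)
            assert res.estimate == pytest.approx(val, abs=1e-8), link

    def test_too_few_clusters_rejected(self):
        d = CRTDataset(np.array(["a", "b"]), np.array([0, 1]), np.array([1.0, 2.0]))
        with pytest.raises(EstimatorError):
            fit_iee(d)


class TestClusterLevel:
    def test_weighted_matches_iee_unweighted(self, toy_dataset):
        res = fit_cluster_level(summarize_clusters(toy_dataset), weighted=True)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.estimand_target == "participant_average"

    def test_unweighted_equals_cluster_mean_contrast(self, toy_dataset):
        res = fit_cluster_level(summarize_clusters(toy_dataset), weighted=False)
        assert res.estimate == pytest.approx(1.5, abs=1e-12)
        assert res.correction == "classical"

    def test_equal_sizes_weighting_irrelevant(self, rng):
        d = random_dataset(rng)
        eq = CRTDataset(
            np.repeat(d.cluster_labels, 5),
            np.repeat(d.cluster_arms, 5),
            rng.normal(size=5 * d.n_clusters),
        )
        s = summarize_clusters(eq)
        assert fit_cluster_level(s, True).estimate == pytest.approx(
            fit_cluster_level(s, False).estimate, abs=1e-12
        )

    def test_weighted_matches_wls_hc0(self, figure1_replicate):
        s = summarize_clusters(figure1_replicate)
        x = sm.add_constant(s.arm.astype(float))
        ref = sm.WLS(s.ybar, x, weights=s.n.astype(float)).fit(cov_type="HC0")
        res = fit_cluster_level(s, weighted=True)
        assert res.estimate == pytest.approx(ref.params[1], abs=1e-10)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-8)

    def test_unweighted_matches_ols_classical(self, figure1_replicate):
        s = summarize_clusters(figure1_replicate)
        x = sm.add_constant(s.arm.astype(float))
        ref = sm.OLS(s.ybar, x).fit()
        res = fit_cluster_level(s, weighted=False)
        assert res.estimate == pytest.approx(ref.params[1], abs=1e-10)
        assert res.se == pytest.approx(ref.bse[1], rel=1e-10)


class TestMixedModel:
    def test_matches_reml_reference(self, figure1_replicate):
        df = figure1_replicate.to_frame()
        ref = smf.mixedlm("outcome ~ arm", df, groups=df["cluster_id"]).fit(reml=True)
        res = fit_mixed_random_intercept(figure1_replicate)
        assert res.estimate == pytest.approx(ref.params["arm"], abs=1e-4)
        assert res.nuisance["sigma_b2"] == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3)
        assert res.nuisance["sigma_e2"] == pytest.approx(ref.scale, rel=1e-3)

    def test_zero_between_cluster_variance_reduces_to_iee(self, rng):
        # outcomes i.i.d. given arm: rho-hat ~ 0 and GLS collapses to OLS
        g = 40
        sizes = rng.integers(2, 9, size=g)
        arms = np.repeat([0, 1], g // 2)
        d = CRTDataset(
            np.repeat([f"g{i}" for i in range(g)], sizes),
            np.repeat(arms, sizes),
            rng.normal(np.repeat(arms, sizes) * 2.0, 1.0),
        )
        res = fit_mixed_random_intercept(d)
        assert res.nuisance["rho"] < 0.05
        at0 = fit_mixed_random_intercept(d, fixed_rho=0.0)
        assert at0.estimate == pytest.approx(fit_iee(d).estimate, abs=1e-10)
        assert "icc_at_boundary" in at0.warnings or at0.nuisance["rho"] == 0.0

    def test_balanced_design_estimate_is_mean_difference(self, rng):
        g, n = 20, 6
        arms = np.repeat([0, 1], g // 2)
        y = rng.normal(np.repeat(arms, n) * 1.5, 1.0, size=g * n) + np.repeat(
            rng.normal(0, 1.0, g), n
        )
        d = CRTDataset(np.repeat([f"g{i}" for i in range(g)], n), np.repeat(arms, n), y)
        diff = y[d.arm == 1].mean() - y[d.arm == 0].mean()
        for rho in (0.0, 0.3, 0.9):
            res = fit_mixed_random_intercept(d, fixed_rho=rho)
            assert res.estimate == pytest.approx(diff, abs=1e-9), rho

    def test_limits_interpolate_between_estimands(self, figure1_replicate):
        # rho -> 0 gives the participant-weighted IEE estimate;
        # rho -> 1 gives the equal-cluster-weight contrast
        d = figure1_replicate
        lo = fit_mixed_random_intercept(d, fixed_rho=0.0)
        assert lo.estimate == pytest.approx(fit_iee(d).estimate, abs=1e-10)
        hi = fit_mixed_random_intercept(d, fixed_rho=0.999)
        cl = fit_cluster_level(summarize_clusters(d), weighted=False)
        assert hi.estimate == pytest.approx(cl.estimate, abs=5e-3)


class TestGEEExchangeable:
    def test_alpha_zero_equals_iee(self, figure1_replicate):
        res = fit_gee_exchangeable(figure1_replicate, alpha=0.0)
        assert res.estimate == pytest.approx(
            fit_iee(figure1_replicate).estimate, abs=1e-10
        )

    def test_matches_reference_gee(self, figure1_replicate):
        df = figure1_replicate.to_frame()
        ref = sm.GEE.from_formula(
            "outcome ~ arm", groups="cluster_id", data=df,
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        res = fit_gee_exchangeable(figure1_replicate)
        assert res.estimate == pytest.approx(ref.params["arm"], abs=1e-6)
        assert res.se == pytest.approx(ref.bse["arm"], rel=1e-6)
        assert res.nuisance["alpha"] == pytest.approx(ref.cov_struct.dep_params, abs=1e-6)

    def test_matches_gls_at_matched_correlation(self, figure1_replicate):
        res = fit_gee_exchangeable(figure1_replicate)
        gls = fit_mixed_random_intercept(
            figure1_replicate, fixed_rho=res.nuisance["alpha"]
        )
        assert res.estimate == pytest.approx(gls.estimate, abs=1e-4)

    def test_binomial_matches_reference(self, rng):
        d = generate_dataset(preset_scenarios("type1-binary"), replicate=1)
        df = d.to_frame()
        ref = sm.GEE.from_formula(
            "outcome ~ arm", groups="cluster_id", data=df,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        res = fit_gee_exchangeable(d, family="binomial")
        assert res.estimate == pytest.approx(ref.params["arm"], abs=1e-4)


class TestSandwich:
    def test_size_one_clusters_reduce_to_hc0(self, rng):
        n = 30
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        e = rng.normal(size=n)
        bread = x.T @ x
        ours = cluster_robust_covariance(e[:, None] * x, bread)
        binv = np.linalg.inv(bread)
        hc0 = binv @ (x.T * e**2) @ x @ binv
        np.testing.assert_allclose(ours, hc0, atol=1e-12)

    def test_matches_textbook_loop_implementation(self, rng):
        d = random_dataset(rng, min_clusters=6)
        x = np.column_stack([np.ones(d.n_participants), d.arm.astype(float)])
        beta = np.linalg.lstsq(x, d.outcome, rcond=None)[0]
        e = d.outcome - x @ beta
        bread = x.T @ x
        # independent elementwise loop over clusters
        meat = np.zeros((2, 2))
        scores = []
        for lab in d.cluster_labels:
            idx = d.cluster == lab
            s = x[idx].T @ e[idx]
            scores.append(s)
            meat += np.outer(s, s)
        expected = np.linalg.inv(bread) @ meat @ np.linalg.inv(bread)
        ours = cluster_robust_covariance(np.array(scores), bread)
        np.testing.assert_allclose(ours, expected, atol=1e-10)

    def test_cr1_scales_se_by_sqrt_g_over_g_minus_1(self, rng):
        d = random_dataset(rng, min_clusters=5)
        r0 = fit_iee(d, opts=FitOptions(variance_correction="CR0"))
        r1 = fit_iee(d, opts=FitOptions(variance_correction="CR1"))
        g = d.n_clusters
        assert r1.se == pytest.approx(r0.se * np.sqrt(g / (g - 1)), rel=1e-12)

    def test_singular_bread_rejected(self):
        with pytest.raises(EstimatorError):
            cluster_robust_covariance(np.ones((5, 2)), np.zeros((2, 2)))

    def test_fewer_than_three_clusters_rejected(self):
        with pytest.raises(EstimatorError):
            cluster_robust_covariance(np.ones((2, 2)), np.eye(2))


class TestEstimatorIdentities:
    @given(st.integers(0, 2**31 - 1))
    def test_weighted_cluster_level_equals_unweighted_iee(self, seed):
        d = random_dataset(np.random.default_rng(seed))
        a = fit_iee(d).estimate
        b = fit_cluster_level(summarize_clusters(d), weighted=True).estimate
        assert a == pytest.approx(b, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_unweighted_cluster_level_equals_weighted_iee(self, seed):
        d = random_dataset(np.random.default_rng(seed))
        a = fit_iee(d, weights="inverse_cluster_size").estimate
        b = fit_cluster_level(summarize_clusters(d), weighted=False).estimate
        assert a == pytest.approx(b, abs=1e-10)

    def test_balanced_design_collapses_all_five(self, rng):
        g, n = 12, 7
        arms = np.repeat([0, 1], g // 2)
        y = rng.normal(np.repeat(arms, n) * 2.0, 1.0, size=g * n)
        d = CRTDataset(np.repeat([f"g{i}" for i in range(g)], n), np.repeat(arms, n), y)
        s = summarize_clusters(d)
        vals = [
            fit_iee(d).estimate,
            fit_iee(d, weights="inverse_cluster_size").estimate,
            fit_cluster_level(s, True).estimate,
            fit_cluster_level(s, False).estimate,
            fit_mixed_random_intercept(d).estimate,
            fit_gee_exchangeable(d).estimate,
        ]
        np.testing.assert_allclose(vals, vals[0], atol=1e-8)


class TestFitOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitOptions(variance_correction="CR2")
        with pytest.raises(ValueError):
            FitOptions(ci_level=1.2)
        with pytest.raises(ValueError):
            FitOptions(tol=0.0)

    def test_normal_vs_t_interval_widths(self, toy_dataset):
        rt = fit_iee(toy_dataset, opts=FitOptions(df_method="t_G_minus_2"))
        rn = fit_iee(toy_dataset, opts=FitOptions(df_method="normal"))
        assert rt.df == toy_dataset.n_clusters - 2
        assert rn.df is None
        assert (rt.ci[1] - rt.ci[0]) > (rn.ci[1] - rn.ci[0])
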