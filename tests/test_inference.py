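"""Mixed-model inference: rank LMM, LRT machinery, paternity GLMM."""
import warnings

import numpy as np
import pandas as pd
import patsy
import pytest
import statsmodels.api as sm
from scipy import integrate, stats
from scipy.special import expit

import coalrank as cr
from coalrank import FittingError, UsageError
from coalrank.experiments import _MLFit
from coalrank.glmm import PaternityGLMM
from coalrank.lmm import (DEFAULT_REDUCTION_ORDER, FixedEffectsSpec,
                          INTERCEPTS_ONLY, RankTrajectoryModel)


@pytest.fixture(scope="module")
def fitted_pair(rank_table):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = RankTrajectoryModel(rank_table,
                                   random_structure=INTERCEPTS_ONLY).fit()
        null = RankTrajectoryModel(rank_table, null=True,
                                   random_structure=INTERCEPTS_ONLY).fit()
    return full, null


class TestFixedEffectsSpec:
    def test_full_minus_null_is_13_parameters(self, rank_table):
        """role(1) + configuration(2) + feasibility(1) + their interactions
        (7) + time(1) + role x time(1) = 13 main-predictor parameters."""
        spec = FixedEffectsSpec()
        d = rank_table.copy()
        _, Xf = patsy.dmatrices(spec.full_formula(), d)
        _, Xn = patsy.dmatrices(spec.null_formula(), d)
        assert Xf.shape[1] - Xn.shape[1] == 13
        assert set(Xn.design_info.column_names) <= set(
            Xf.design_info.column_names)

    def test_null_contains_no_main_predictor_terms(self):
        spec = FixedEffectsSpec()
        for token in ("role", "configuration", "feas", "days"):
            assert token not in spec.null_formula()


class TestRankTrajectoryModel:
    def test_results_surface(self, fitted_pair):
        full, _ = fitted_pair
        assert np.isfinite(full.llf)
        assert (full.bse > 0).all()
        assert full.converged
        assert set(full.vcomp) == set(INTERCEPTS_ONLY)
        text = full.summary()
        assert "Rank trajectory LMM" in text and "coef" in text

    def test_constant_response_rejected(self, rank_table):
        d = rank_table.copy()
        d["future_rating"] = 1000.0
        with pytest.raises(FittingError, match="constant"):
            RankTrajectoryModel(d)

    def test_degenerate_table_rejected(self, rank_table):
        with pytest.raises(UsageError):
            RankTrajectoryModel(rank_table.iloc[:1])

    def test_reduction_order_documented_and_recorded(self, rank_table,
                                                     monkeypatch):
        """When slope structures fail, slopes are dropped in the documented
        order and the reduction is recorded on the results object."""
        model = RankTrajectoryModel(rank_table)
        original = RankTrajectoryModel._fit_once

        def failing(self, structure, reml, maxiter, polish=True):
            slope_keys = [k for k in DEFAULT_REDUCTION_ORDER if k in structure]
            if slope_keys:
                raise np.linalg.LinAlgError("forced failure")
            return original(self, structure, reml, maxiter, polish)

        monkeypatch.setattr(RankTrajectoryModel, "_fit_once", failing)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        expected = [k for k in DEFAULT_REDUCTION_ORDER
                    if k in model.random_structure]
        assert res.reduction == expected
        assert set(res.structure) == {"male", "event"}

    def test_prediction_uses_fixed_effects_only(self, fitted_pair, rank_table):
        full, _ = fitted_pair
        pred = full.predict(rank_table)
        assert len(pred) == len(rank_table)
        assert np.isfinite(pred).all()


class TestLikelihoodRatioTest:
    def test_identical_models_give_zero_statistic(self, fitted_pair):
        full, _ = fitted_pair
        res = cr.likelihood_ratio_test(full, full)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_statistic_is_twice_loglik_difference(self):
        full = _MLFit(llf=-100.0, df_fixed=5, fixed_names=list("abcde"),
                      nobs=50)
        null = _MLFit(llf=-107.4, df_fixed=2, fixed_names=list("ab"), nobs=50)
        res = cr.likelihood_ratio_test(full, null)
        assert res.statistic == pytest.approx(2 * 7.4)
        assert res.df == 3
        assert res.pvalue == pytest.approx(stats.chi2.sf(14.8, 3))

    def test_full_vs_null_on_simulated_world(self, fitted_pair):
        full, null = fitted_pair
        res = cr.likelihood_ratio_test(full, null)
        assert res.df == 13
        assert res.statistic >= 0
        # injected effects at default size: the test should clearly reject
        assert res.pvalue < 0.05

    def test_non_nested_models_rejected(self, rank_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = RankTrajectoryModel(
                rank_table,
                spec=FixedEffectsSpec(controls=("day0_z",)),
                random_structure=INTERCEPTS_ONLY).fit()
            null = RankTrajectoryModel(
                rank_table,
                spec=FixedEffectsSpec(controls=("day0_z", "age_z")),
                null=True, random_structure=INTERCEPTS_ONLY).fit()
        with pytest.raises(UsageError, match="not nested"):
            cr.likelihood_ratio_test(full, null)

    def test_reml_fits_rejected(self, rank_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reml = RankTrajectoryModel(
                rank_table, random_structure=INTERCEPTS_ONLY).fit(reml=True)
            ml = RankTrajectoryModel(
                rank_table, null=True,
                random_structure=INTERCEPTS_ONLY).fit()
        with pytest.raises(UsageError, match="ML"):
            cr.likelihood_ratio_test(reml, ml)

    def test_statistic_invariant_under_affine_reparameterization(
            self, rank_table):
        """Rescaling a continuous predictor leaves the LRT unchanged."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base_full = RankTrajectoryModel(
                rank_table, random_structure=INTERCEPTS_ONLY).fit()
            base_null = RankTrajectoryModel(
                rank_table, null=True,
                random_structure=INTERCEPTS_ONLY).fit()
            scaled = rank_table.copy()
            scaled["feas_z"] = 3.0 * scaled["feas_z"] + 1.0
            alt_full = RankTrajectoryModel(
                scaled, random_structure=INTERCEPTS_ONLY).fit()
            alt_null = RankTrajectoryModel(
                scaled, null=True, random_structure=INTERCEPTS_ONLY).fit()
        s0 = cr.likelihood_ratio_test(base_full, base_null).statistic
        s1 = cr.likelihood_ratio_test(alt_full, alt_null).statistic
        assert s1 == pytest.approx(s0, abs=0.05)


class TestPaternityGLMM:
    def _direct_loglike(self, model, beta, sd):
        total = 0.0
        for rows in model._group_rows:
            eta0 = model.exog[rows] @ beta
            y = model.endog[rows]

            def integrand(b):
                p = expit(eta0 + b)
                lik = np.prod(p ** y * (1 - p) ** (1 - y))
                return lik * np.exp(-b ** 2 / (2 * sd ** 2)) / np.sqrt(
                    2 * np.pi * sd ** 2)

            total += np.log(integrate.quad(integrand, -12 * sd, 12 * sd)[0])
        return total

    def test_quadrature_matches_direct_integration(self):
        """Adaptive GHQ log-likelihood agrees with brute-force quadrature on
        a 3-male toy within 1e-3."""
        cohort = cr.simulate_paternity_cohort(cr.PaternitySimConfig(
            n_conceptions=5, candidates_per_conception=3, male_re_sd=0.8),
            seed=21)
        model = PaternityGLMM.from_formula("sired ~ rating", cohort,
                                           groups="male")
        for beta, sd in [(np.array([-1.0, 0.8]), 0.7),
                         (np.array([0.2, -0.5]), 0.25),
                         (np.array([-2.5, 1.43]), 1.2)]:
            ghq = model.loglike(np.concatenate([beta, [np.log(sd)]]))
            direct = self._direct_loglike(model, beta, sd)
            assert abs(ghq - direct) < 1e-3

    def test_degenerate_random_effect_matches_plain_logistic(self):
        rng = np.random.default_rng(31)
        n, males = 3000, 25
        rating = rng.uniform(size=n)
        male = rng.integers(males, size=n)
        eta = -2.0 + 1.5 * rating
        y = (rng.random(n) < expit(eta)).astype(float)
        df = pd.DataFrame({"sired": y, "rating": rating,
                           "male": [f"M{i}" for i in male],
                           "infant": [f"I{i % 100}" for i in range(n)]})
        res = PaternityGLMM.from_formula("sired ~ rating", df,
                                         groups="male").fit()
        glm = sm.GLM(y, sm.add_constant(rating),
                     family=sm.families.Binomial()).fit()
        assert res.params["Intercept"] == pytest.approx(glm.params[0],
                                                        abs=1e-3)
        assert res.params["rating"] == pytest.approx(glm.params[1], abs=1e-3)

    def test_zero_slope_recovered_as_zero(self):
        rng = np.random.default_rng(41)
        estimates = []
        for _ in range(40):
            cohort = cr.simulate_paternity_cohort(cr.PaternitySimConfig(
                slope=0.0), seed=int(rng.integers(2 ** 31)))
            res = PaternityGLMM.from_formula("sired ~ rating", cohort,
                                             groups="male").fit()
            estimates.append(res.params["rating"])
        mean = np.mean(estimates)
        mc_se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(mean) <= 3 * mc_se

    def test_paternity_lrt_has_one_degree_of_freedom(self):
        cohort = cr.simulate_paternity_cohort(seed=51)
        full = PaternityGLMM.from_formula("sired ~ rating", cohort,
                                          groups="male").fit()
        null = PaternityGLMM.from_formula("sired ~ 1", cohort,
                                          groups="male").fit()
        res = cr.likelihood_ratio_test(full, null)
        assert res.df == 1
        assert res.statistic >= 0

    def test_complete_separation_raises(self):
        cohort = cr.simulate_paternity_cohort(seed=61)
        cohort["sired"] = (cohort["rating"] > 0.5).astype(int)
        with pytest.raises(FittingError, match="separat"):
            PaternityGLMM.from_formula("sired ~ rating", cohort,
                                       groups="male").fit()

    def test_fit_paternity_model_with_controls(self, small_world):
        pop = small_world["population"]
        traj = small_world["trajectories"]
        conc = cr.simulate_conceptions(
            pop, traj, cr.PaternitySimConfig(n_conceptions=8), seed=71)
        pat = cr.build_paternity_dataset(conc, traj, pop.presence)
        res = cr.fit_paternity_model(pat)
        assert "rating" in res.params.index
        assert res.params.index[-1] == "re_sd"
        assert np.isfinite(res.llf)
        assert "Paternity GLMM" in res.summary()
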