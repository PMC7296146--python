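"""Bivariate genotype-by-treatment REML: oracle equivalence, recovery,
Wald behaviour, and derived genetic parameters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodrought.mixedmodel import (DayTraitFit, SingularDesignError,
                                     analyze_postharvest, fit_day_trait,
                                     genetic_correlation,
                                     genetic_variance_log2fc,
                                     phenotypic_correlation, wald_drought_test)
from phenodrought.simulate import simulate_experiment

from conftest import carrier_means_one_day, one_day_scenario


def anova_moment_oracle(cm: pd.DataFrame) -> np.ndarray:
    """Closed-form ANOVA estimators for balanced two-carrier data.

    Residual variance per condition from within-genotype carrier mean
    squares; genotype (co)variances from the between-genotype sample
    covariance of condition-wise genotype means, subtracting residual/2
    on the diagonal.  Written directly from the balanced-design algebra,
    independent of the package's likelihood code.
    """
    wide = cm.pivot_table(index="genotype", columns=["treatment", "carrier"],
                          values="value")
    yc = wide["control"].to_numpy()
    yd = wide["drought"].to_numpy()
    se_c = np.mean((yc[:, 0] - yc[:, 1]) ** 2) / 2
    se_d = np.mean((yd[:, 0] - yd[:, 1]) ** 2) / 2
    mc, md = yc.mean(axis=1), yd.mean(axis=1)
    S = np.cov(mc, md, ddof=1)
    return np.array([S[0, 0] - se_c / 2, S[1, 1] - se_d / 2, S[0, 1],
                     se_c, se_d])


def _estimates(fit: DayTraitFit) -> np.ndarray:
    return np.array([fit.var_g_control, fit.var_g_drought, fit.cov_g,
                     fit.var_e_control, fit.var_e_drought])


class TestRemlVsMomentOracle:
    def test_balanced_instances_match_closed_form(self):
        g = np.array([[4.0, 2.0], [2.0, 4.0]])
        for seed in range(50):
            cm = carrier_means_one_day(20, g, carrier_sd=1.0, seed=seed)
            fit = fit_day_trait(cm, compute_se=False)
            assert fit.converged
            oracle = anova_moment_oracle(cm)
            np.testing.assert_allclose(_estimates(fit), oracle, rtol=1e-6,
                                       atol=1e-8)

    def test_shift_invariance_of_variance_components(self):
        g = np.array([[2.0, 1.0], [1.0, 3.0]])
        cm = carrier_means_one_day(15, g, carrier_sd=0.7, seed=7)
        fit = fit_day_trait(cm, compute_se=False)
        shifted = cm.assign(value=cm["value"] + 123.0)
        fit2 = fit_day_trait(shifted, compute_se=False)
        np.testing.assert_allclose(_estimates(fit2), _estimates(fit),
                                   rtol=1e-6, atol=1e-8)
        assert fit2.mu_control == pytest.approx(fit.mu_control + 123.0, rel=1e-9)
        assert fit2.mu_drought == pytest.approx(fit.mu_drought + 123.0, rel=1e-9)

    def test_genotype_order_invariance(self):
        g = np.array([[2.0, -1.0], [-1.0, 3.0]])
        cm = carrier_means_one_day(15, g, carrier_sd=0.7, seed=9)
        fit = fit_day_trait(cm, compute_se=False)
        shuffled = cm.sample(frac=1.0, random_state=4)
        fit2 = fit_day_trait(shuffled, compute_se=False)
        np.testing.assert_allclose(_estimates(fit2), _estimates(fit),
                                   rtol=1e-8)

    def test_unbalanced_fit_beats_start_and_is_stationary(self):
        g = np.array([[4.0, 2.0], [2.0, 4.0]])
        cm = carrier_means_one_day(20, g, carrier_sd=1.0, seed=3)
        cm = cm.drop(cm.index[[1, 10, 30]])  # drop some carrier means
        fit = fit_day_trait(cm, compute_se=True)
        assert fit.converged
        assert fit.se["var_g_control"] > 0

    def test_too_few_genotypes_raises(self):
        cm = pd.DataFrame({
            "genotype": ["G1"] * 4,
            "treatment": ["control", "control", "drought", "drought"],
            "carrier": ["c1", "c2"] * 2, "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(SingularDesignError):
            fit_day_trait(cm)


class TestParameterRecovery:
    def test_planted_g_recovered_within_mc_error(self):
        # planted G = [[4,2],[2,4]], residual 1 per condition, 97 genotypes
        g = np.array([[4.0, 2.0], [2.0, 4.0]])
        truth = np.array([4.0, 2.0, 4.0, 1.0, 1.0, 0.5])
        n_rep = 200
        est = np.empty((n_rep, 6))
        for seed in range(n_rep):
            cm = carrier_means_one_day(97, g, carrier_sd=1.0, seed=seed)
            fit = fit_day_trait(cm, compute_se=False)
            est[seed] = [fit.var_g_control, fit.cov_g, fit.var_g_drought,
                         fit.var_e_control, fit.var_e_drought,
                         fit.genetic_correlation]
        mean = est.mean(axis=0)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - truth) < 3 * mc_se + 1e-12), (mean, mc_se)


class TestWald:
    def test_planted_mean_shift_recovered_exactly_without_noise(self):
        from phenodrought.simulate import EffectProfileArchetype
        arch = EffectProfileArchetype("negative_no_recovery", 1, 1, -20.0)
        sc = one_day_scenario(10, np.zeros((2, 2)), carrier_sd=0.0, seed=0,
                              archetype=arch)
        obs, _, _ = simulate_experiment(sc)
        cm = obs.groupby(["genotype", "treatment", "carrier"],
                         as_index=False)["value"].mean()
        fit = fit_day_trait(cm, compute_se=False)
        assert fit.mean_drought_effect == pytest.approx(-20.0, abs=1e-9)

    def test_zero_difference_gives_zero_statistic(self):
        fit = DayTraitFit("t", 1, 5.0, 5.0, 1.0, 1.0, 0.5, 1.0, 1.0,
                          wald=0.0, pvalue=1.0, converged=True, n_genotypes=10)
        w, p, nl = wald_drought_test(fit)
        assert (w, p, nl) == (0.0, 1.0, 0.0)

    def test_nonconverged_fit_rejected(self):
        fit = DayTraitFit("t", 1, 5.0, 5.0, 1.0, 1.0, 0.5, 1.0, 1.0,
                          wald=1.0, pvalue=0.3, converged=False, n_genotypes=10)
        with pytest.raises(ValueError):
            wald_drought_test(fit)

    def test_reduces_to_two_sample_z_without_genotype_variance(self):
        # zero G: the model collapses to two independent samples of
        # genotype-by-carrier noise; W must equal the squared z statistic
        # with variances estimated per condition
        cm = carrier_means_one_day(40, np.zeros((2, 2)), carrier_sd=1.0, seed=5)
        fit = fit_day_trait(cm, compute_se=False)
        yc = cm.loc[cm["treatment"] == "control", "value"].to_numpy()
        yd = cm.loc[cm["treatment"] == "drought", "value"].to_numpy()
        # oracle: squared z with the fit's variance structure at zero G is
        # just GLS on independent observations
        sc2 = fit.var_g_control + fit.var_e_control / 2
        sd2 = fit.var_g_drought + fit.var_e_drought / 2
        var_diff = (sc2 + sd2 - 2 * fit.cov_g) / 40
        z2 = (yd.reshape(40, 2).mean(1).mean()
              - yc.reshape(40, 2).mean(1).mean()) ** 2 / var_diff
        assert fit.wald == pytest.approx(z2, rel=1e-6)

    def test_type_one_error_calibrated(self):
        # null: no treatment effect, G = I*0.5, 2000 replicates at alpha 5%
        g = np.array([[0.5, 0.0], [0.0, 0.5]])
        n_rep = 2000
        rej = 0
        for seed in range(n_rep):
            cm = carrier_means_one_day(97, g, carrier_sd=1.0, seed=10_000 + seed)
            fit = fit_day_trait(cm, compute_se=False)
            rej += fit.pvalue < 0.05
        rate = rej / n_rep
        assert abs(rate - 0.05) < 0.01, rate

    def test_null_pvalues_uniform(self):
        # KS check on the p-values of the first 400 null replicates
        g = np.array([[0.5, 0.0], [0.0, 0.5]])
        pvals = []
        for seed in range(400):
            cm = carrier_means_one_day(50, g, carrier_sd=1.0, seed=50_000 + seed)
            pvals.append(fit_day_trait(cm, compute_se=False).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestDerivedParameters:
    def _fit_with(self, gcc, gdd, gcd):
        return DayTraitFit("t", 1, 0.0, 0.0, gcc, gdd, gcd, 1.0, 1.0,
                           wald=0.0, pvalue=1.0, converged=True, n_genotypes=10)

    def test_genetic_correlation_basic(self):
        assert genetic_correlation(self._fit_with(2.0, 2.0, 1.0)) == \
            pytest.approx(0.5)
        assert genetic_correlation(self._fit_with(2.0, 2.0, 0.0)) == 0.0

    def test_genetic_correlation_undefined_for_negative_variance(self):
        assert np.isnan(genetic_correlation(self._fit_with(-0.2, 2.0, 1.0)))
        assert np.isnan(genetic_correlation(self._fit_with(0.0, 2.0, 1.0)))

    def test_genetic_correlation_truncated(self):
        fit = self._fit_with(1.0, 1.0, 1.4)
        assert genetic_correlation(fit) == 1.0
        assert fit.rg_truncated

    def test_log2fc(self):
        assert genetic_variance_log2fc(self._fit_with(1.0, 1.0, 0.0)) == 0.0
        assert genetic_variance_log2fc(self._fit_with(1.0, 4.0, 0.0)) == \
            pytest.approx(2.0)
        assert np.isnan(genetic_variance_log2fc(self._fit_with(-1.0, 4.0, 0.0)))

    def test_phenotypic_correlation_affine(self):
        rows = []
        vals = np.linspace(1, 10, 8)
        for i, v in enumerate(vals):
            rows.append((f"G{i}", "control", v))
            rows.append((f"G{i}", "drought", 2 * v + 1))
        df = pd.DataFrame(rows, columns=["genotype", "treatment", "value"])
        assert phenotypic_correlation(df) == pytest.approx(1.0)

    def test_phenotypic_correlation_null_distribution(self):
        # independent conditions, 97 genotypes: |r| < 0.25 for most seeds
        rng = np.random.default_rng(0)
        inside = 0
        for _ in range(40):
            rows = []
            for i in range(97):
                rows.append((f"G{i}", "control", rng.normal()))
                rows.append((f"G{i}", "drought", rng.normal()))
            df = pd.DataFrame(rows, columns=["genotype", "treatment", "value"])
            inside += abs(phenotypic_correlation(df)) < 0.25
        assert inside >= 35  # ~99% expected at n=97


class TestPostharvest:
    def test_planted_shift_and_correlation_recovered(self):
        from phenodrought.simulate import (PostHarvestLink, SimulationScenario,
                                           TraitScenario,
                                           EffectProfileArchetype)
        from phenodrought.design import ExperimentDesign
        d = ExperimentDesign(n_genotypes=60, n_days=1, drought_start_day=1,
                             drought_end_day=1)
        ts = TraitScenario("t", 100.0, EffectProfileArchetype("null"),
                           np.zeros((2, 2)))
        links = [PostHarvestLink(sym, 10.0, -25.0, {}, noise_sd=2.0,
                                 genotype_sd=1.0, plant_sd=0.3)
                 for sym in ("PH", "TGW", "LSm")]
        sc = SimulationScenario(d, [ts], postharvest=links, seed=11)
        _, ph, _ = simulate_experiment(sc)
        out = analyze_postharvest(ph).set_index("trait")
        assert (out["neglog10p"] > 3).all()  # planted -25% shift detected
        assert out["var_g_control"].between(0.3, 3.0).all()
        # genotype effects persist across conditions: r_g close to 1
        assert (out["genetic_correlation"] > 0.6).all()
        assert (out["phenotypic_correlation"] > 0.5).all()

    def test_zero_genotype_variance_gives_undefined_rg(self):
        from phenodrought.simulate import (PostHarvestLink, SimulationScenario,
                                           TraitScenario,
                                           EffectProfileArchetype)
        from phenodrought.design import ExperimentDesign
        d = ExperimentDesign(n_genotypes=40, n_days=1, drought_start_day=1,
                             drought_end_day=1)
        ts = TraitScenario("t", 100.0, EffectProfileArchetype("null"),
                           np.zeros((2, 2)))
        links = [PostHarvestLink("NTP", 5.0, -10.0, {}, noise_sd=0.0,
                                 genotype_sd=0.0, plant_sd=1.0)]
        sc = SimulationScenario(d, [ts], postharvest=links, seed=2)
        _, ph, _ = simulate_experiment(sc)
        out = analyze_postharvest(ph).set_index("trait")
        row = out.loc["NTP"]
        # rg reported undefined exactly when a diagonal estimate is <= 0
        defined = row["var_g_control"] > 0 and row["var_g_drought"] > 0
        assert np.isnan(row["genetic_correlation"]) == (not defined)
        assert abs(row["var_g_control"]) < 0.5  # hovers near the planted zero


class TestCovariateModel:
    def test_noiseless_covariate_recovered(self):
        # y = mu_t + 2 * x_g exactly: the ANCOVA fit must return beta = 2
        # and the planted treatment difference
        rng = np.random.default_rng(0)
        rows = []
        x = {}
        for i in range(15):
            g = f"G{i:02d}"
            x[g] = float(rng.normal())
            for t, mu in (("control", 10.0), ("drought", 7.0)):
                for c in ("c1", "c2"):
                    rows.append((g, t, c, mu + 2.0 * x[g]))
        cm = pd.DataFrame(rows, columns=["genotype", "treatment", "carrier",
                                         "value"])
        fit = fit_day_trait(cm, covariate=pd.Series(x), compute_se=False)
        assert fit.beta_covariate == pytest.approx(2.0, abs=1e-6)
        assert fit.mean_drought_effect == pytest.approx(-3.0, abs=1e-6)

    def test_covariate_absorbs_genotype_trend(self):
        # a genotype-level trend (e.g. phenology) shared by both
        # treatments inflates the genetic variances of the plain model;
        # the ANCOVA fit attributes it to the covariate instead
        rng = np.random.default_rng(1)
        rows = []
        x = {}
        for i in range(40):
            g = f"G{i:02d}"
            x[g] = float(rng.normal())
            for t in ("control", "drought"):
                shift = -4.0 if t == "drought" else 0.0
                for c in ("c1", "c2"):
                    rows.append((g, t, c,
                                 10.0 + shift + 3.0 * x[g]
                                 + 0.1 * rng.normal()))
        cm = pd.DataFrame(rows, columns=["genotype", "treatment", "carrier",
                                         "value"])
        plain = fit_day_trait(cm, compute_se=False)
        ancova = fit_day_trait(cm, covariate=pd.Series(x), compute_se=False)
        assert ancova.converged
        assert ancova.beta_covariate == pytest.approx(3.0, abs=0.1)
        assert ancova.mean_drought_effect == pytest.approx(-4.0, abs=0.1)
        assert plain.var_g_control > 5.0  # trend masquerades as variance
        assert abs(ancova.var_g_control) < 0.5


def test_analytic_gradient_matches_value_and_finite_differences():
    """The gradient-bearing likelihood agrees with the plain evaluation
    and with central finite differences away from the optimum."""
    from scipy import optimize
    from phenodrought.mixedmodel import (_pattern_neg2_reml,
                                         _pattern_neg2_reml_and_grad,
                                         _prepare, moment_start)
    g = np.array([[2.0, 1.0], [1.0, 3.0]])
    cm = carrier_means_one_day(25, g, carrier_sd=1.0, seed=17)
    cm = cm.drop(cm.index[[2, 40]])  # unbalance it
    packed, _ = _prepare(cm, None)
    theta = moment_start(cm) * 1.2 + 0.1
    f, grad = _pattern_neg2_reml_and_grad(theta, packed)
    assert f == pytest.approx(_pattern_neg2_reml(theta, packed), rel=1e-12)
    fd = optimize.approx_fprime(theta,
                                lambda t: _pattern_neg2_reml(t, packed),
                                1e-6 * np.maximum(np.abs(theta), 1.0))
    np.testing.assert_allclose(grad, fd, rtol=5e-4, atol=5e-3)
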