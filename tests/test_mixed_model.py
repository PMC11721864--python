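"""Crossed random-intercepts REML fit and fixed-effect inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autosegeval import fit_crossed_model, generate_metric_table
from autosegeval.mixed_model import _profiled_criterion
from autosegeval.mixed_model import test_fixed_effect as fixed_effect_test

from ._oracles import ems_components_three_way

PARAMS = dict(beta0=0.8, beta1=-0.02, sigma2_patient=0.005,
              sigma2_observer=0.002, sigma2_residual=0.004,
              n_patients=20, n_observers=3)


def make_table(seed, **over):
    return generate_metric_table(dict(PARAMS, **over), seed=seed, response="y")


class TestBalancedExactness:
    def test_beta1_equals_arm_mean_difference(self):
        tab = make_table(3)
        fit = fit_crossed_model(tab, "y")
        hp = tab[tab.imaging_system == "high_performance"]["y"].mean()
        conv = tab[tab.imaging_system == "conventional"]["y"].mean()
        assert fit.beta1 == pytest.approx(hp - conv, abs=1e-9)

    def test_paired_p_matches_scipy_paired_ttest(self):
        tab = make_table(8)
        fit = fit_crossed_model(tab, "y")
        wide = tab.pivot_table(index=["patient_id", "observer_id"],
                               columns="imaging_system", values="y")
        res = stats.ttest_rel(wide["high_performance"], wide["conventional"])
        assert fit.p_value == pytest.approx(res.pvalue, abs=1e-6)
        assert fit.df == len(wide) - 1

    def test_reml_loglik_not_below_moment_start(self):
        # the optimiser must do at least as well as the ANOVA starting point
        tab = make_table(12)
        fit = fit_crossed_model(tab, "y")
        y = tab["y"].to_numpy()
        pat, _ = pd.factorize(tab.patient_id, sort=True)
        obs, _ = pd.factorize(tab.observer_id, sort=True)
        x = (tab.imaging_system == "high_performance").to_numpy(float)
        X = np.column_stack([np.ones(len(y)), x])
        Zp = np.eye(pat.max() + 1)[pat]
        Zo = np.eye(obs.max() + 1)[obs]
        s2p, s2o, s2e = ems_components_three_way(tab, "y")
        crit_start, _ = _profiled_criterion(np.log([s2p / s2e, s2o / s2e]),
                                            y, Zp, Zo, X, ["p", "o"])
        crit_fit, _ = _profiled_criterion(
            np.log([max(fit.sigma2_patient, 1e-12) / fit.sigma2_residual,
                    max(fit.sigma2_observer, 1e-12) / fit.sigma2_residual]),
            y, Zp, Zo, X, ["p", "o"])
        assert crit_fit <= crit_start + 1e-9

    def test_zero_random_effects_reduce_to_pooled_regression(self):
        # project patient and observer structure out of the residuals so the
        # moment estimates are negative -> truncated to zero with refit
        rng = np.random.default_rng(99)
        a, b = 10, 4
        e = rng.normal(0, 0.1, size=(a, 2, b))
        e -= e.mean(axis=(1, 2), keepdims=True)
        e -= e.mean(axis=(0, 1), keepdims=True)
        y = 0.7 + 0.05 * np.array([0, 1.0])[None, :, None] + e
        ii, kk, jj = np.meshgrid(range(a), range(2), range(b), indexing="ij")
        tab = pd.DataFrame({
            "patient_id": ii.ravel(), "observer_id": jj.ravel(),
            "imaging_system": np.array(["conventional", "high_performance"])[kk.ravel()],
            "y": y.ravel()})
        fit = fit_crossed_model(tab, "y", inference="satterthwaite")
        assert fit.sigma2_patient == 0.0 and fit.sigma2_observer == 0.0
        # pooled two-group OLS standard error
        yv = tab["y"].to_numpy()
        x = (tab.imaging_system == "high_performance").to_numpy(float)
        n1, n0 = int(x.sum()), int((1 - x).sum())
        rss = ((yv[x == 1] - yv[x == 1].mean()) ** 2).sum() \
            + ((yv[x == 0] - yv[x == 0].mean()) ** 2).sum()
        s2 = rss / (len(yv) - 2)
        assert fit.se_beta1 == pytest.approx(np.sqrt(s2 * (1 / n1 + 1 / n0)), abs=1e-9)

    def test_symmetric_data_gives_null_result(self):
        # identical responses in both arms: beta1 = 0 exactly, t = 0, p = 1
        base = make_table(5)
        sym = base.copy()
        wide = sym.pivot_table(index=["patient_id", "observer_id"],
                               columns="imaging_system", values="y")
        lookup = wide.mean(axis=1)
        sym["y"] = [lookup[(p, o)] for p, o in zip(sym.patient_id, sym.observer_id)]
        fit = fit_crossed_model(sym, "y")
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)
        res = fixed_effect_test(fit)
        assert res["t_statistic"] == 0.0
        assert res["p_value"] == 1.0


class TestRemlVsClosedForm:
    def test_interior_components_match_ems_oracle(self):
        # interior-safe design: 8 observers -> truncation essentially impossible
        for seed in range(5):
            tab = generate_metric_table(
                dict(beta0=0.8, beta1=-0.02, sigma2_patient=0.005,
                     sigma2_observer=0.004, sigma2_residual=0.004,
                     n_patients=10, n_observers=8), seed=seed, response="y")
            fit = fit_crossed_model(tab, "y")
            s2p, s2o, s2e = ems_components_three_way(tab, "y")
            assert fit.sigma2_patient == pytest.approx(s2p, abs=1e-6)
            assert fit.sigma2_observer == pytest.approx(s2o, abs=1e-6)
            assert fit.sigma2_residual == pytest.approx(s2e, abs=1e-6)


@pytest.fixture(scope="module")
def unbalanced():
    tab = make_table(4)
    return tab.drop(tab.index[[3, 17, 44, 88, 101]])


class TestUnbalanced:

    def test_satterthwaite_matches_lmerTest_reference(self, unbalanced):
        # frozen reference from R lmerTest on this exact table:
        # beta 0.02862227 (se 0.01132314), df 92.266147, p 0.01317936
        fit = fit_crossed_model(unbalanced, "y")
        assert fit.inference == "satterthwaite"
        assert fit.beta1 == pytest.approx(0.02862227, abs=1e-7)
        assert fit.se_beta1 == pytest.approx(0.01132314, abs=1e-7)
        assert fit.df == pytest.approx(92.266147, rel=2e-3)
        assert fit.p_value == pytest.approx(0.01317936, rel=1e-3)

    def test_variance_components_match_lmerTest_reference(self, unbalanced):
        fit = fit_crossed_model(unbalanced, "y")
        assert fit.sigma2_patient == pytest.approx(0.0048671, abs=2e-6)
        assert fit.sigma2_observer == pytest.approx(0.0016336, abs=2e-6)
        assert fit.sigma2_residual == pytest.approx(0.0036579, abs=2e-6)


def test_statsmodels_cross_check():
    """Independent route: statsmodels MixedLM with crossed variance components
    must agree on the fixed effect and components (cross-check only)."""
    import statsmodels.formula.api as smf

    tab = make_table(21)
    fit = fit_crossed_model(tab, "y")
    tab = tab.assign(x=(tab.imaging_system == "high_performance").astype(float), g=1)
    md = smf.mixedlm("y ~ x", tab, groups="g",
                     vc_formula={"pat": "0 + C(patient_id)",
                                 "obs": "0 + C(observer_id)"})
    sm_fit = md.fit(reml=True, method="lbfgs")
    assert fit.beta1 == pytest.approx(sm_fit.params["x"], abs=1e-5)
    assert fit.sigma2_patient == pytest.approx(sm_fit.vcomp[0], abs=1e-5)
    assert fit.sigma2_observer == pytest.approx(sm_fit.vcomp[1], abs=1e-5)
    assert fit.sigma2_residual == pytest.approx(sm_fit.scale, abs=1e-5)


def test_parameter_recovery_over_simulations():
    """Mean beta1 within 3 MC se of truth and component means within 15%
    over 200 simulated default-design datasets."""
    fits = [fit_crossed_model(make_table(40000 + s), "y") for s in range(200)]
    b1 = np.array([f.beta1 for f in fits])
    # coding: beta1 reported as hp - conv = -PARAMS beta1 (conv - hp)
    assert abs(b1.mean() - 0.02) < 3 * b1.std(ddof=1) / np.sqrt(len(b1))
    for attr, truth in (("sigma2_patient", 0.005), ("sigma2_observer", 0.002),
                        ("sigma2_residual", 0.004)):
        m = np.mean([getattr(f, attr) for f in fits])
        assert m == pytest.approx(truth, rel=0.15)


def test_input_validation():
    tab = make_table(1)
    with pytest.raises(ValueError):
        fit_crossed_model(tab[tab.observer_id == "O1"], "y")
    with pytest.raises(ValueError):
        fit_crossed_model(tab[tab.imaging_system == "conventional"], "y")
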