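"""FIML Cholesky engine: covariance algebra, likelihood, fitting, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinsat.cholesky import (CholeskyModelSpec, CholeskyTwinModel,
                              aic_from_fit, build_sex_limitation,
                              compare_models, expected_pair_covariance,
                              lrt_arithmetic)
from twinsat.simulate import apply_single_responders, simulate_cohort
from twinsat.truth import CohortDesign, univariate_truth


def _ae_spec(variables, mode="equal_across_sex", comps=("A", "E")):
    return CholeskyModelSpec(tuple(variables), tuple(comps), mode)


# ---------------------------------------------------------------------------
# expected pair covariance
# ---------------------------------------------------------------------------

class TestExpectedPairCovariance:
    def test_pure_genetic_univariate(self):
        prm = {"A": np.array([[1.0]]), "E": np.array([[0.0]])}
        mz = expected_pair_covariance(prm, "MZ")
        dz = expected_pair_covariance(prm, "DZ")
        assert mz[0, 1] == pytest.approx(1.0)
        assert dz[0, 1] == pytest.approx(0.5)

    def test_ace_univariate(self):
        prm = {"A": np.array([[np.sqrt(0.4)]]),
               "C": np.array([[np.sqrt(0.2)]]),
               "E": np.array([[np.sqrt(0.4)]])}
        mz = expected_pair_covariance(prm, "MZ")
        dz = expected_pair_covariance(prm, "DZ")
        assert mz[0, 0] == pytest.approx(1.0)
        assert mz[0, 1] == pytest.approx(0.6)
        assert dz[0, 1] == pytest.approx(0.4)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_and_twin_exchangeability(self, seed, p):
        """The pair covariance is symmetric and invariant to which twin is
        listed first (swapping the two p-blocks)."""
        rng = np.random.default_rng(seed)
        prm = {c: np.tril(rng.normal(size=(p, p))) for c in ("A", "C", "E")}
        for zyg in ("MZ", "DZ"):
            sig = expected_pair_covariance(prm, zyg)
            assert np.allclose(sig, sig.T)
            perm = np.r_[np.arange(p, 2 * p), np.arange(p)]
            assert np.allclose(sig, sig[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# FIML likelihood
# ---------------------------------------------------------------------------

def _dense_oracle_m2ll(model, theta):
    """Independent dense-likelihood oracle: sum of -2 log N(y; mu, Sigma)
    over complete pairs via scipy's multivariate normal."""
    params = model.layout.unpack(theta)
    total = 0.0
    p = model.spec.p
    for b in model._blocks:
        sigma = expected_pair_covariance(params[b.sex], b.zygosity)
        sub = sigma[np.ix_(b.idx, b.idx)]
        mu = np.tile(params["means"][b.sex], 2)[b.idx]
        for row in b.Y:
            total += -2.0 * stats.multivariate_normal.logpdf(row, mu, sub)
    return total


@pytest.fixture(scope="module")
def bivariate_model(bivariate_ae_truth, balanced_design):
    cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
    spec = _ae_spec(("X", "Y"))
    return CholeskyTwinModel(cohort, spec, zscore=False)


class TestFiml:
    def test_matches_dense_oracle_on_complete_data(self, bivariate_model):
        theta = bivariate_model._start_theta()
        got = bivariate_model.minus2ll(theta)
        want = _dense_oracle_m2ll(bivariate_model, theta)
        assert got == pytest.approx(want, abs=1e-8)

    def test_single_responder_marginalization(self, bivariate_ae_truth):
        """A single-responder pair contributes the p-dimensional marginal
        of the observed twin."""
        design = CohortDesign(n_mz_m=30, n_dz_m=30, n_mz_f=30, n_dz_f=30,
                              single_responder_rate=0.0, seed=1)
        cohort = simulate_cohort(bivariate_ae_truth, design)
        cohort = apply_single_responders(cohort, ("X", "Y"), 0.3, seed=2)
        model = CholeskyTwinModel(cohort, _ae_spec(("X", "Y")), zscore=False)
        theta = model._start_theta()
        assert model.minus2ll(theta) == pytest.approx(
            _dense_oracle_m2ll(model, theta), abs=1e-8)

    def test_additivity_under_duplication(self, bivariate_ae_truth,
                                          balanced_design):
        """Duplicating every pair exactly doubles the -2LL (the likelihood
        is a sum over independent pairs)."""
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        doubled = pd.concat([cohort, cohort.assign(
            pair_id=cohort["pair_id"] + "b")], ignore_index=True)
        spec = _ae_spec(("X", "Y"))
        m1 = CholeskyTwinModel(cohort, spec, zscore=False)
        m2 = CholeskyTwinModel(doubled, spec, zscore=False)
        theta = m1._start_theta()
        assert m2.minus2ll(theta) == pytest.approx(2 * m1.minus2ll(theta),
                                                   rel=1e-12)

    def test_twin_order_permutation_invariance(self, bivariate_ae_truth,
                                               balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        swapped = cohort.copy()
        for v in ("X", "Y"):
            swapped[f"{v}_t1"], swapped[f"{v}_t2"] = (
                cohort[f"{v}_t2"], cohort[f"{v}_t1"])
        spec = _ae_spec(("X", "Y"))
        m1 = CholeskyTwinModel(cohort, spec, zscore=False)
        m2 = CholeskyTwinModel(swapped, spec, zscore=False)
        theta = m1._start_theta()
        assert m1.minus2ll(theta) == pytest.approx(m2.minus2ll(theta),
                                                   rel=1e-12)


# ---------------------------------------------------------------------------
# sex-limitation parameter maps
# ---------------------------------------------------------------------------

class TestSexLimitation:
    def test_free_parameter_counts_trivariate_ae(self):
        """Hand-counted free parameters: 6 paths per triangular matrix for
        p = 3, means free per sex."""
        p, t = 3, 6
        counts = {"equal_across_sex": 2 * t + 2 * p,
                  "scalar_sex_limitation": 2 * t + p + 2 * p,
                  "common_sex_limitation": 2 * 2 * t + 2 * p}
        for mode, expect in counts.items():
            layout = build_sex_limitation(_ae_spec(("a", "b", "c"), mode))
            assert layout.n_free == expect

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="sex_mode"):
            CholeskyModelSpec(("a",), ("A", "E"), "diagonal_sex_limitation")

    def test_e_component_mandatory(self):
        with pytest.raises(ValueError, match="E component"):
            CholeskyModelSpec(("a",), ("A",))

    def test_scalar_with_unit_scales_equals_equal_mode(self, bivariate_model,
                                                       bivariate_ae_truth,
                                                       balanced_design):
        """With all scale factors fixed at one, the scalar sex-limitation
        likelihood is exactly the equal-across-sex likelihood."""
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        spec_eq = _ae_spec(("X", "Y"), "equal_across_sex")
        spec_sc = _ae_spec(("X", "Y"), "scalar_sex_limitation")
        m_eq = CholeskyTwinModel(cohort, spec_eq, zscore=False)
        m_sc = CholeskyTwinModel(cohort, spec_sc, zscore=False)
        sex_params = {s: {"A": bivariate_ae_truth.paths("A"),
                          "C": np.zeros((2, 2)),
                          "E": bivariate_ae_truth.paths("E")} for s in "MF"}
        means = {s: np.zeros(2) for s in "MF"}
        th_eq = m_eq.layout.pack(sex_params, means)
        th_sc = m_sc.layout.pack(sex_params, means, scale_F=np.ones(2))
        assert m_sc.minus2ll(th_sc) == pytest.approx(m_eq.minus2ll(th_eq),
                                                     rel=1e-14)

    def test_common_mode_with_equal_branches_matches_equal_mode(
            self, bivariate_ae_truth, balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        m_eq = CholeskyTwinModel(cohort, _ae_spec(("X", "Y")), zscore=False)
        m_co = CholeskyTwinModel(
            cohort, _ae_spec(("X", "Y"), "common_sex_limitation"),
            zscore=False)
        sex_params = {s: {"A": bivariate_ae_truth.paths("A"),
                          "C": np.zeros((2, 2)),
                          "E": bivariate_ae_truth.paths("E")} for s in "MF"}
        means = {s: np.zeros(2) for s in "MF"}
        assert m_co.minus2ll(m_co.layout.pack(sex_params, means)) == \
            pytest.approx(m_eq.minus2ll(m_eq.layout.pack(sex_params, means)),
                          rel=1e-14)

    def test_scalar_fit_has_equal_standardized_components_across_sex(
            self, bivariate_ae_truth, balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        fit = CholeskyTwinModel(
            cohort, _ae_spec(("X", "Y"), "scalar_sex_limitation")).fit(
                n_restarts=1)
        m = fit.standardized_components(sex="M")
        f = fit.standardized_components(sex="F")
        assert np.allclose(m.to_numpy(), f.to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_aic_identity_and_df_accounting(self, bivariate_ae_truth,
                                            balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        cohort = apply_single_responders(cohort, ("X", "Y"), 0.15, seed=3)
        model = CholeskyTwinModel(cohort, _ae_spec(("X", "Y")))
        fit = model.fit(n_restarts=1)
        n_points = int(cohort[["X_t1", "X_t2", "Y_t1", "Y_t2"]].notna()
                       .to_numpy().sum())
        assert fit.n_obs_points == n_points
        assert fit.df == n_points - fit.n_free
        assert fit.aic == fit.minus2ll - 2 * fit.df  # exact arithmetic

    def test_saturated_model_bounds_structured_fit(self, bivariate_ae_truth,
                                                   balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        model = CholeskyTwinModel(cohort, _ae_spec(("X", "Y")), zscore=False)
        fit = model.fit(n_restarts=1)
        assert model.saturated_minus2ll() <= fit.minus2ll + 1e-6

    def test_variable_order_invariance_of_fit(self, bivariate_ae_truth,
                                              balanced_design):
        """Reordering the variables changes path labels but not the optimum
        -2LL (the implied covariances are order-independent)."""
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        f1 = CholeskyTwinModel(cohort, _ae_spec(("X", "Y"))).fit(n_restarts=2)
        f2 = CholeskyTwinModel(cohort, _ae_spec(("Y", "X"))).fit(n_restarts=2)
        assert f1.minus2ll == pytest.approx(f2.minus2ll, abs=1e-4)

    def test_ml_agrees_with_falconer_on_large_cohort(
            self, univariate_cohort_large):
        """Univariate equal-sex AE ML heritability matches the Falconer
        moment estimate within sampling error (generating a2 = 0.5)."""
        from twinsat.descriptives import (falconer_heritability,
                                          twin_cotwin_correlations)
        fit = CholeskyTwinModel(univariate_cohort_large,
                                _ae_spec(("LS",))).fit(n_restarts=1)
        tab = twin_cotwin_correlations(univariate_cohort_large, ("LS",))
        falc = falconer_heritability(tab.loc["LS", "rMZ"],
                                     tab.loc["LS", "rDZ"]).value
        assert fit.h2("LS") == pytest.approx(falc, abs=0.03)
        assert fit.h2("LS") == pytest.approx(0.5, abs=0.03)

    def test_ae_data_fitted_with_ace_drives_c_to_zero(self):
        """On AE-generated data the ACE fit returns c2 ~ 0 and the AE model
        wins on AIC."""
        truth = univariate_truth(0.5)
        design = CohortDesign(n_mz_m=500, n_dz_m=500, n_mz_f=500, n_dz_f=500,
                              single_responder_rate=0.0, seed=17)
        cohort = simulate_cohort(truth, design)
        ace = CholeskyTwinModel(cohort, _ae_spec(("LS",), comps=("A", "C", "E"))
                                ).fit(n_restarts=2)
        ae = CholeskyTwinModel(cohort, _ae_spec(("LS",))).fit(n_restarts=2)
        c2 = float(ace.standardized_components().loc["LS", "c2"])
        assert c2 < 0.05
        assert ae.aic < ace.aic

    def test_missing_zygosity_rejected(self, bivariate_ae_truth):
        design = CohortDesign(n_mz_m=20, n_dz_m=1, n_mz_f=20, n_dz_f=0,
                              single_responder_rate=0.0, seed=5)
        cohort = simulate_cohort(bivariate_ae_truth, design)
        only_mz = cohort[cohort["zygosity"] == "MZ"]
        with pytest.raises(ValueError, match="MZ and DZ"):
            CholeskyTwinModel(only_mz, _ae_spec(("X", "Y")))

    def test_summary_renders(self, bivariate_ae_truth, balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        fit = CholeskyTwinModel(cohort, _ae_spec(("X", "Y"))).fit(n_restarts=1)
        text = fit.summary()
        assert "-2LL" in text and "AIC" in text and "X" in text


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

class TestComparison:
    def test_lrt_published_arithmetic(self):
        delta, ddf, p = lrt_arithmetic(6571.21, 6570.32, 4505, 4493)
        assert delta == pytest.approx(0.89)
        assert ddf == 12
        assert p > 0.99

    def test_base_compared_with_itself(self):
        delta, ddf, p = lrt_arithmetic(100.0, 100.0, 50, 50)
        assert delta == 0 and ddf == 0 and p == 1.0

    def test_compare_models_flags_best_by_aic(self, bivariate_ae_truth,
                                              balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        ace = CholeskyTwinModel(
            cohort, _ae_spec(("X", "Y"), comps=("A", "C", "E"))).fit(
                n_restarts=1)
        ae = CholeskyTwinModel(cohort, _ae_spec(("X", "Y"))).fit(n_restarts=1)
        tab = compare_models([ace, ae])
        assert tab["delta_minus2ll"].iloc[0] == 0
        assert tab["p"].iloc[0] == 1.0
        assert tab.loc[tab["best"], "aic"].iloc[0] == tab["aic"].min()
        assert (tab["delta_df"] >= 0).all()

    def test_non_nested_comparison_warns(self, bivariate_ae_truth,
                                         balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        ace = CholeskyTwinModel(
            cohort, _ae_spec(("X", "Y"), comps=("A", "C", "E"))).fit(
                n_restarts=1)
        ae = CholeskyTwinModel(cohort, _ae_spec(("X", "Y"))).fit(n_restarts=1)
        with pytest.warns(UserWarning, match="more free parameters"):
            tab = compare_models([ae, ace])
        assert np.isnan(tab["p"].iloc[1])

    def test_aic_helper(self):
        assert aic_from_fit(6570.32, 4493) == pytest.approx(-2415.68)


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def univariate_fit():
    truth = univariate_truth(0.5)
    design = CohortDesign(n_mz_m=150, n_dz_m=150, n_mz_f=150, n_dz_f=150,
                          single_responder_rate=0.0, seed=23)
    cohort = simulate_cohort(truth, design)
    return CholeskyTwinModel(cohort, _ae_spec(("LS",))).fit(n_restarts=1)


class TestProfileCI:
    def test_interval_contains_point_estimate(self, univariate_fit):
        ci = univariate_fit.profile_ci("h2:LS")
        assert ci.lower <= univariate_fit.h2("LS") <= ci.upper

    def test_interval_width_shrinks_with_sample_size(self, univariate_fit):
        truth = univariate_truth(0.5)
        big = CohortDesign(n_mz_m=600, n_dz_m=600, n_mz_f=600, n_dz_f=600,
                           single_responder_rate=0.0, seed=24)
        fit_big = CholeskyTwinModel(simulate_cohort(truth, big),
                                    _ae_spec(("LS",))).fit(n_restarts=1)
        ci_small = univariate_fit.profile_ci("h2:LS")
        ci_big = fit_big.profile_ci("h2:LS")
        w_small = ci_small.upper - ci_small.lower
        w_big = ci_big.upper - ci_big.lower
        # 4x the pairs -> roughly half the width
        assert w_big < 0.75 * w_small

    def test_genetic_correlation_interval(self, bivariate_ae_truth,
                                          balanced_design):
        cohort = simulate_cohort(bivariate_ae_truth, balanced_design)
        fit = CholeskyTwinModel(cohort, _ae_spec(("X", "Y"))).fit(n_restarts=1)
        ci = fit.profile_ci("rg:X,Y", level=0.90)
        rg = float(fit.component_correlations("A").loc["X", "Y"])
        assert ci.lower <= rg <= ci.upper
        assert -1.0 <= ci.lower and ci.upper <= 1.0
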