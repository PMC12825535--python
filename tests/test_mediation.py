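"""Four-way decomposition: closed form vs quadrature, limits, recovery, PCA."""

import numpy as np
import pandas as pd
import pytest

from prediagprot.mediation_fourway import (
    FourWaySpec,
    decompose,
    encode_exposure,
    exposure_associations,
    fit_models,
    four_way_components,
    mediate_via_pca,
    pca_aggregate,
    screen_mediators,
)
from prediagprot.synthetic_cohort import MediationSpec, SimConfig, simulate_cohort

COMPONENTS = ("te", "cde", "int_ref", "int_med", "pie")


def quadrature_Q(a, ap, beta0, beta1, sigma2, theta1, theta2, theta3, cov_term=0.0, n_nodes=80):
    """Independent oracle: E[g(a, M)] with M ~ N(mu(ap), sigma2) by
    Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    mu = beta0 + beta1 * ap + cov_term
    m = mu + np.sqrt(sigma2) * nodes
    g = np.exp(theta1 * a + theta2 * m + theta3 * a * m)
    return float((weights * g).sum() / np.sqrt(2 * np.pi))


def quadrature_components(params, a=1.0, a_star=0.0, m_star=0.0):
    Q = lambda aa, ap: quadrature_Q(aa, ap, **params)
    g = lambda aa, m: np.exp(
        params["theta1"] * aa + params["theta2"] * m + params["theta3"] * aa * m
    )
    D = Q(a_star, a_star)
    return {
        "te": (Q(a, a) - D) / D,
        "cde": (g(a, m_star) - g(a_star, m_star)) / D,
        "int_ref": (Q(a, a_star) - D - g(a, m_star) + g(a_star, m_star)) / D,
        "int_med": (Q(a, a) - Q(a_star, a) - Q(a, a_star) + D) / D,
        "pie": (Q(a_star, a) - D) / D,
    }


def _random_params(rng):
    return dict(
        beta0=rng.uniform(-1, 1),
        beta1=rng.uniform(-1, 1),
        sigma2=rng.uniform(0.2, 2.0),
        theta1=rng.uniform(-0.8, 0.8),
        theta2=rng.uniform(-0.8, 0.8),
        theta3=rng.uniform(-0.4, 0.4),
    )


class TestClosedForm:
    def test_additivity_over_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p = _random_params(rng)
            c = four_way_components(**p, m_star=rng.uniform(-1, 1))
            gap = abs(c["cde"] + c["int_ref"] + c["int_med"] + c["pie"] - c["te"])
            assert gap < 1e-10

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = _random_params(rng)
            m_star = rng.uniform(-1, 1)
            closed = four_way_components(**p, m_star=m_star)
            quad = quadrature_components(p, m_star=m_star)
            for k in COMPONENTS:
                denom = max(abs(quad[k]), 1e-12)
                assert abs(closed[k] - quad[k]) / denom < 1e-8

    def test_beta1_zero_kills_pie_and_intmed_exactly(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = _random_params(rng)
            p["beta1"] = 0.0
            c = four_way_components(**p, m_star=rng.uniform(-1, 1))
            assert c["pie"] == 0.0 and c["int_med"] == 0.0

    def test_theta3_zero_interaction_components_follow_err_algebra(self):
        """With no product term the ERR-scale interaction components do not
        vanish; they collapse to the documented closed forms."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = _random_params(rng)
            p["theta3"] = 0.0
            m_star = rng.uniform(-1, 1)
            c = four_way_components(**p, m_star=m_star)
            da = 1.0
            mu_ref = p["beta0"]
            want_med = (np.exp(p["theta1"] * da) - 1) * (
                np.exp(p["theta2"] * p["beta1"] * da) - 1
            )
            want_ref = (np.exp(p["theta1"] * da) - 1) * (
                1 - np.exp(p["theta2"] * (m_star - mu_ref) - p["theta2"] ** 2 * p["sigma2"] / 2)
            )
            assert c["int_med"] == pytest.approx(want_med, abs=1e-12)
            assert c["int_ref"] == pytest.approx(want_ref, abs=1e-12)


@pytest.fixture(scope="module")
def fitted(mediation_cohort):
    cohort, matrix, truth = mediation_cohort
    models = fit_models(cohort, "bmi", "P0001", covariates=["age", "sex"], matrix=matrix)
    return cohort, matrix, truth, models


class TestFitModels:
    def test_parameter_recovery(self, fitted):
        _, _, truth, models = fitted
        med = truth.mediation
        assert models.beta1 == pytest.approx(med["beta1"], abs=0.05)
        assert models.sigma2 == pytest.approx(med["sigma2"], rel=0.1)
        se = models.cox_fit.se
        assert abs(models.theta1 - med["theta1"]) < 3 * se[0]
        assert abs(models.theta2 - med["theta2"]) < 3 * se[1]
        assert abs(models.theta3 - med["theta3"]) < 3 * se[2]

    def test_permuted_exposure_is_null(self, mediation_cohort):
        cohort, matrix, _ = mediation_cohort
        rng = np.random.default_rng(0)
        shuffled = cohort.copy()
        shuffled["bmi"] = rng.permutation(shuffled["bmi"].to_numpy())
        models = fit_models(shuffled, "bmi", "P0001", covariates=[], matrix=matrix)
        assert abs(models.beta1) < 2.5 * np.sqrt(models.ols_cov[1, 1])
        assert abs(models.theta1) < 2.5 * models.cox_fit.se[0]

    def test_constant_mediator_rejected(self, mediation_cohort):
        cohort, _, _ = mediation_cohort
        bad = cohort.assign(flat=1.0)
        with pytest.raises(ValueError):
            fit_models(bad, "bmi", "flat", covariates=[])

    def test_high_event_fraction_warns(self):
        cfg = SimConfig(
            n_participants=2000, n_proteins=2, event_rate=0.2,
            mediation_spec=MediationSpec(mediators={"P0001": 0.5}, theta2=0.3),
            missing_rate=0.0, seed=4,
        )
        cohort, matrix, _ = simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="rare-outcome"):
            fit_models(cohort, "bmi", "P0001", covariates=[], matrix=matrix)


class TestDecompose:
    def test_bootstrap_additivity_and_ci(self, fitted):
        _, _, _, models = fitted
        res = decompose(models, FourWaySpec(n_boot=60, seed=5))
        gap = abs(
            res.estimates["cde"] + res.estimates["int_ref"] + res.estimates["int_med"]
            + res.estimates["pie"] - res.estimates["te"]
        )
        assert gap < 1e-10
        for k in COMPONENTS:
            assert res.ci_low[k] <= res.estimates[k] <= res.ci_high[k]

    def test_recovers_true_proportion(self, fitted):
        _, _, truth, models = fitted
        res = decompose(models, FourWaySpec(n_boot=120, seed=6))
        lo, hi = res.proportion_mediated_ci
        assert lo <= truth.mediation["proportion_mediated"] <= hi

    def test_delta_method_close_to_bootstrap(self, fitted):
        _, _, _, models = fitted
        boot = decompose(models, FourWaySpec(n_boot=120, seed=7))
        delta = decompose(models, FourWaySpec(ci_method="delta"))
        assert delta.estimates == boot.estimates
        for k in COMPONENTS:
            if boot.se[k] > 1e-4:
                assert delta.se[k] == pytest.approx(boot.se[k], rel=0.6)

    def test_binary_and_continuous_paths_agree_on_01_exposure(self, mediation_cohort):
        """A 0/1-valued exposure gives identical results under both codings."""
        cohort, matrix, _ = mediation_cohort
        cohort = cohort.copy()
        cohort["flag"] = (cohort["smoking"] == "ever").astype(float)
        m_bin = fit_models(cohort, "flag", "P0002", covariates=[], matrix=matrix,
                           exposure_kind="binary")
        a_cont, _ = encode_exposure(cohort, "flag", "binary")
        cohort["flag2"] = a_cont
        m_cont = fit_models(cohort, "flag2", "P0002", covariates=[], matrix=matrix,
                            exposure_kind="binary")
        spec = FourWaySpec(n_boot=0, ci_method="delta")
        r1 = decompose(m_bin, spec)
        r2 = decompose(m_cont, spec)
        for k in COMPONENTS:
            assert r1.estimates[k] == pytest.approx(r2.estimates[k], abs=1e-12)

    def test_proportion_invariant_to_mediator_rescaling(self, mediation_cohort):
        cohort, matrix, _ = mediation_cohort
        scaled = matrix.copy()
        scaled["P0001"] = 5.0 * scaled["P0001"] + 2.0
        spec = FourWaySpec(ci_method="delta")
        r1 = decompose(fit_models(cohort, "bmi", "P0001", covariates=[], matrix=matrix), spec)
        r2 = decompose(fit_models(cohort, "bmi", "P0001", covariates=[], matrix=scaled), spec)
        assert r1.proportion_mediated == pytest.approx(r2.proportion_mediated, abs=1e-6)

    def test_significance_rule(self, fitted):
        _, _, _, models = fitted
        res = decompose(models, FourWaySpec(n_boot=120, seed=8))
        assert res.significant == (res.p["te"] < 0.05 and res.p["pie"] < 0.05)


class TestScreening:
    def test_both_legs_required(self):
        expo = pd.Series({"A": 0.2, "B": 1e-5, "C": 1e-5})
        outc = pd.Series({"A": 1e-5, "B": 1e-5, "C": 0.5})
        assert screen_mediators(expo, outc) == ["B"]

    def test_null_generator_candidate_rate(self):
        """Independent legs: expected candidate count ~ 24 * alpha^2."""
        rng = np.random.default_rng(11)
        n_sims, hits = 200, 0
        for _ in range(n_sims):
            expo = pd.Series(rng.uniform(size=24), index=range(24))
            outc = pd.Series(rng.uniform(size=24), index=range(24))
            hits += len(screen_mediators(expo, outc))
        # Poisson-ish: mean 24*0.0025=0.06 per sim -> 12 expected over 200
        assert hits < 30

    def test_exposure_associations_detects_mediator(self, mediation_cohort):
        cohort, matrix, _ = mediation_cohort
        assoc = exposure_associations(cohort, matrix, "bmi", covariates=["age", "sex"])
        assert assoc.loc["P0001", "p"] < 1e-10
        assert assoc.loc["P0003", "p"] > 0.001


def test_interaction_mediator_filter_drops_significant_intmed():
    from prediagprot.mediation_fourway import FourWayResult, filter_interaction_mediators

    def fake(name, p_int):
        est = {"te": 1.0, "cde": 0.5, "int_ref": 0.0, "int_med": 0.1, "pie": 0.4}
        return FourWayResult(
            exposure="smoking", mediator=name, estimates=est, se={}, ci_low={},
            ci_high={}, p={"int_med": p_int}, proportion_mediated=0.4,
            proportion_mediated_ci=None, total_mediated=0.5, significant=True,
        )

    kept = filter_interaction_mediators([fake("ok", 0.4), fake("drop", 0.01)])
    assert [r.mediator for r in kept] == ["ok"]


class TestPCA:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        m = pd.DataFrame({"a": x, "b": 2 * x + 1})
        out = pca_aggregate(m)
        assert out.retained == ["PC1"]
        assert out.eigenvalues[0] == pytest.approx(2.0)
        assert abs(out.loadings.loc["a", "PC1"]) == pytest.approx(
            abs(out.loadings.loc["b", "PC1"])
        )
        assert out.scores["PC1"].std(ddof=1) == pytest.approx(1.0)

    def test_independent_mediators_keep_about_half(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.standard_normal((2000, 8)))
        m.columns = [f"m{i}" for i in range(8)]
        out = pca_aggregate(m)
        assert 1 <= len(out.retained) <= 8
        assert np.all(np.abs(out.eigenvalues - 1.0) < 0.3)

    def test_opposing_sign_mediator_excluded(self):
        from prediagprot.mediation_fourway import FourWayResult

        def fake(name, pie, cde):
            est = {"te": 1.0, "cde": cde, "int_ref": 0.0, "int_med": 0.0, "pie": pie}
            return FourWayResult(
                exposure="bmi", mediator=name, estimates=est, se={}, ci_low={},
                ci_high={}, p={}, proportion_mediated=pie, proportion_mediated_ci=None,
                total_mediated=pie, significant=True,
            )

        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.standard_normal((100, 3)), columns=["x", "y", "bad"])
        out = pca_aggregate(m, [fake("x", 0.2, 0.5), fake("y", 0.1, 0.4), fake("bad", 0.2, -0.5)])
        assert out.excluded == ["bad"]
        assert list(out.loadings.index) == ["x", "y"]


class TestMediateViaPca:
    def test_single_component_equals_direct_decompose(self, mediation_cohort):
        cohort, matrix, _ = mediation_cohort
        rng = np.random.default_rng(3)
        m = matrix[["P0001"]].copy()
        m["echo"] = m["P0001"] * 2 + 0.05 * rng.standard_normal(len(m))
        pca = pca_aggregate(m)
        assert pca.retained == ["PC1"]
        spec = FourWaySpec(ci_method="delta")
        results, combined = mediate_via_pca(cohort, pca.scores, "bmi",
                                            covariates=["age"], spec=spec)
        direct = decompose(
            fit_models(cohort.join(pca.scores), "bmi", "PC1", covariates=["age"]), spec
        )
        assert results[0].estimates == direct.estimates
        assert combined == results[0].proportion_mediated

    def test_mediated_share_recovered_through_pca(self, mediation_cohort):
        cohort, matrix, truth = mediation_cohort
        rng = np.random.default_rng(4)
        m = matrix[["P0001"]].copy()
        m["echo"] = m["P0001"] + 0.2 * rng.standard_normal(len(m))
        pca = pca_aggregate(m)
        results, combined = mediate_via_pca(
            cohort, pca.scores, "bmi", covariates=[], spec=FourWaySpec(n_boot=80, seed=9)
        )
        assert combined == pytest.approx(truth.mediation["proportion_mediated"], abs=0.25)

    def test_null_exposure_combined_proportion_covers_zero(self, mediation_cohort):
        cohort, matrix, _ = mediation_cohort
        rng = np.random.default_rng(5)
        shuffled = cohort.copy()
        shuffled["bmi"] = rng.permutation(shuffled["bmi"].to_numpy())
        m = matrix[["P0002", "P0003"]]
        pca = pca_aggregate(m)
        results, _ = mediate_via_pca(
            shuffled, pca.scores, "bmi", covariates=[], spec=FourWaySpec(n_boot=80, seed=10)
        )
        for r in results:
            lo, hi = r.ci_low["pie"], r.ci_high["pie"]
            assert lo <= 0.0 <= hi
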