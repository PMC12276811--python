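import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.optimize import minimize_scalar

from tunnelpref.inference import (
    BetaBinomFit,
    ModelSpec,
    estimate_group_means,
    fit_betabinom_mixed,
    likelihood_ratio_test,
    linear_contrast,
    pairwise_contrasts,
    predict_run_effects,
    sidak_adjust,
    ModelError,
)


def simulate_records(rng, n_runs=40, per_run=8, mu=0.5, phi=6.0, sigma=0.4,
                     trials=50, group_effect=0.0):
    """Beta-binomial mixed records with a two-level factor."""
    rows = []
    for j in range(n_runs):
        u = rng.normal(0, sigma) if sigma > 0 else 0.0
        for i in range(per_run):
            g = "a" if i % 2 == 0 else "b"
            eta = logit(mu) + u + (group_effect if g == "b" else 0.0)
            p = rng.beta(expit(eta) * phi, (1 - expit(eta)) * phi) if phi < 1e8 \
                else expit(eta)
            rows.append({"run_id": f"R{j}", "grp": g,
                         "successes": int(rng.binomial(trials, p)),
                         "trials": trials})
    return pd.DataFrame(rows)


def fit(df, terms=(), random="intercept_per_run", **kw):
    kw.setdefault("quadrature_nodes", 8)
    return fit_betabinom_mixed(df, ModelSpec("preference", terms, random=random),
                               successes="successes", trials="trials", **kw)


class TestFitting:
    def test_single_group_binomial_closed_form(self):
        df = pd.DataFrame({"run_id": ["R0"], "successes": [400], "trials": [1000]})
        f = fit(df, random="none", dispersion="binomial")
        assert f.coef[0] == pytest.approx(logit(0.4), abs=1e-6)
        assert math.isinf(f.phi) and f.rho == 0.0

    def test_zero_run_variance_estimated_at_boundary(self, rng):
        df = simulate_records(rng, sigma=0.0, phi=1e9, n_runs=40)
        f = fit(df, dispersion="binomial")
        assert f.sigma2_run < 1e-2

    def test_binomial_limit_matches_irls_glm_oracle(self, rng):
        """With dispersion and run variance pinned off, the fit must equal an
        ordinary logistic GLM fitted by IRLS (statsmodels)."""
        import statsmodels.api as sm

        df = simulate_records(rng, sigma=0.0, phi=1e9, group_effect=0.6)
        f = fit(df, terms=("grp",), random="none", dispersion="binomial")
        X = f.design.matrix(f.data)
        endog = np.column_stack([df["successes"], df["trials"] - df["successes"]])
        oracle = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(f.coef, oracle.params, atol=1e-4)

    def test_parameter_recovery_within_wald_intervals(self):
        rng = np.random.default_rng(0)
        mu, phi, sigma = 0.6, 5.0, 0.5
        df = simulate_records(rng, n_runs=200, per_run=10, mu=mu, phi=phi,
                              sigma=sigma, trials=40)
        f = fit(df, quadrature_nodes=20)
        se = f.bse()
        assert abs(f.coef[0] - logit(mu)) < 1.96 * se[0]
        assert abs(math.log(f.phi) - math.log(phi)) < 1.96 * se[1]
        assert abs(0.5 * math.log(f.sigma2_run) - math.log(sigma)) < 1.96 * se[2]

    def test_all_zero_trials_is_an_error(self):
        df = pd.DataFrame({"run_id": ["R0"], "successes": [0], "trials": [0]})
        with pytest.raises(ModelError):
            fit(df)

    def test_label_swap_negates_logit_estimates(self, rng):
        df = simulate_records(rng, mu=0.62, group_effect=0.5, n_runs=25)
        swapped = df.assign(successes=df["trials"] - df["successes"])
        f1 = fit(df, terms=("grp",))
        f2 = fit(swapped, terms=("grp",))
        np.testing.assert_allclose(f1.coef, -f2.coef, atol=1e-3)


class TestLRT:
    def test_identical_models_give_zero(self, rng):
        df = simulate_records(rng, n_runs=15)
        f = fit(df)
        chi2, dof, p = likelihood_ratio_test(f, f)
        assert chi2 == pytest.approx(0.0, abs=1e-8) and p == 1.0

    def test_chi2_tail_reference_value(self):
        """chi2 = 12.55 on 10 df must give p close to 0.25."""
        spec = ModelSpec("preference", ("grp",))
        mk = lambda ll, k: BetaBinomFit(
            spec=spec, coef=np.zeros(1), coef_names=["(Intercept)"], phi=5.0,
            sigma2_run=0.1, loglik=ll, n_obs=100, n_params=k, converged=True,
            quadrature_nodes=8, dispersion="betabinom", design=None, data=None,
        )
        chi2, dof, p = likelihood_ratio_test(mk(-100.0, 13), mk(-106.275, 3))
        assert chi2 == pytest.approx(12.55)
        assert p == pytest.approx(0.25, abs=0.005)

    def test_non_nested_models_rejected(self, rng):
        df = simulate_records(rng, n_runs=10)
        df["other"] = "x"
        f1 = fit(df, terms=("grp",))
        f2 = fit(df, terms=("other",))
        with pytest.raises(ModelError):
            likelihood_ratio_test(f1, f2)

    def test_invariant_to_reference_level_recoding(self, rng):
        df = simulate_records(rng, n_runs=25, group_effect=0.4)
        f1 = fit(df, terms=("grp",))
        f0 = fit(df)
        chi2_a, _, _ = likelihood_ratio_test(f1, f0)
        flipped = df.sort_values("grp", ascending=False,
                                 kind="stable").reset_index(drop=True)
        chi2_b, _, _ = likelihood_ratio_test(fit(flipped, terms=("grp",)),
                                             fit(flipped))
        assert chi2_a == pytest.approx(chi2_b, abs=1e-4)


class TestSidak:
    def test_family_of_one_is_identity(self):
        p = np.array([0.2, 0.8])
        np.testing.assert_allclose(sidak_adjust(p, m=1), p)

    def test_reference_value(self):
        assert sidak_adjust([0.01], m=10)[0] == pytest.approx(1 - 0.99 ** 10)

    def test_boundaries(self):
        np.testing.assert_allclose(sidak_adjust([0.0, 1.0], m=5), [0.0, 1.0])

    def test_grid_matches_direct_evaluation(self):
        ps = np.linspace(0, 1, 21)
        for m in (1, 2, 5, 10, 50):
            np.testing.assert_allclose(sidak_adjust(ps, m=m),
                                       np.clip(1 - (1 - ps) ** m, 0, 1),
                                       atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        assert np.all(sidak_adjust(p) >= p - 1e-15)


class TestGroupMeans:
    def test_intercept_at_half_gives_pi_zero(self):
        df = pd.DataFrame({"run_id": ["R0"], "grp": ["a"],
                           "successes": [500], "trials": [1000]})
        f = fit(df, random="none", dispersion="binomial")
        m = estimate_group_means(f, "grp")
        assert m["pi"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_logit_three_quarters_gives_pi_half(self):
        df = pd.DataFrame({"run_id": ["R0"], "grp": ["a"],
                           "successes": [750], "trials": [1000]})
        f = fit(df, random="none", dispersion="binomial")
        m = estimate_group_means(f, "grp")
        assert m["pi"].iloc[0] == pytest.approx(0.5, abs=1e-6)

    def test_ci_matches_parametric_bootstrap(self, rng):
        df = simulate_records(rng, n_runs=20, group_effect=0.5)
        f = fit(df, terms=("grp",))
        m = estimate_group_means(f, "grp")
        # bootstrap the coefficient sampling distribution
        draws = rng.multivariate_normal(f.coef, f.cov_coef, size=100_000)
        X = f.design.matrix(f.data)
        for _, row in m.iterrows():
            mask = (f.data["grp"] == row["grp"]).to_numpy()
            xbar = X[mask].mean(axis=0)
            qs = np.quantile(expit(draws @ xbar), [0.025, 0.975])
            assert row["prop_lo"] == pytest.approx(qs[0], abs=0.01)
            assert row["prop_hi"] == pytest.approx(qs[1], abs=0.01)

    def test_unknown_grouping_rejected(self, rng):
        f = fit(simulate_records(rng, n_runs=8))
        with pytest.raises(ModelError):
            estimate_group_means(f, "nope")


class TestRunPredictions:
    def test_zero_variance_shrinks_to_group_mean(self, rng):
        df = simulate_records(rng, sigma=0.0, phi=1e9, n_runs=30)
        f = fit(df, dispersion="binomial")
        preds = predict_run_effects(f)
        mean_p = expit(f.coef[0])
        np.testing.assert_allclose(preds["prop"], mean_p, atol=0.02)

    def test_extreme_run_prediction_between_raw_and_pooled(self, rng):
        df = simulate_records(rng, n_runs=20, mu=0.5, sigma=0.3)
        # one run with extreme data
        extra = pd.DataFrame({"run_id": ["Rx"] * 4, "grp": ["a", "b"] * 2,
                              "successes": [48, 49, 50, 47], "trials": [50] * 4})
        f = fit(pd.concat([df, extra], ignore_index=True))
        preds = predict_run_effects(f)
        px = preds.loc[preds["run_id"] == "Rx", "prop"].iloc[0]
        raw = 194 / 200
        pooled = expit(f.coef[0])
        assert min(raw, pooled) <= px <= max(raw, pooled)
        assert px > pooled  # pulled toward its own extreme data

    def test_modes_match_scalar_optimizer_oracle(self, rng):
        df = simulate_records(rng, n_runs=12, per_run=6)
        f = fit(df, quadrature_nodes=20)
        lik = f._lik
        eta0 = lik.X @ f.coef
        sig2 = f.sigma2_run
        for j in range(lik.J):
            mask = lik.ci == j

            def neg_cond(u):
                from tunnelpref.inference import _bb_loglik
                mu = np.clip(expit(eta0[mask] + u), 1e-10, 1 - 1e-10)
                return -(np.sum(_bb_loglik(lik.y[mask], lik.n[mask], mu, f.phi))
                         - u * u / (2 * sig2))

            res = minimize_scalar(neg_cond, bounds=(-5, 5), method="bounded",
                                  options={"xatol": 1e-10})
            assert f.u_hat[j] == pytest.approx(res.x, abs=1e-6)

    def test_nonconverged_fit_is_refused(self, rng):
        f = fit(simulate_records(rng, n_runs=8))
        f.converged = False
        with pytest.raises(Exception):
            predict_run_effects(f)


class TestContrasts:
    def test_pairwise_sidak_family_is_the_call(self, rng):
        df = simulate_records(rng, n_runs=20, group_effect=0.8)
        f = fit(df, terms=("grp",))
        out = pairwise_contrasts(f, "grp")
        assert len(out) == 1
        assert np.all(out["p_adjusted"] >= out["p_raw"] - 1e-15)
        raw = pairwise_contrasts(f, "grp", adjust="none")
        np.testing.assert_allclose(raw["p_adjusted"], raw["p_raw"])
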