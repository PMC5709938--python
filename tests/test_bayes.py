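"""MCMC estimator: posterior math, conjugate draws, composite wiring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import popsse as p
from popsse.bayes import MCMCSettings, fit_bayes, fit_bayes_composite, log_posterior, mcse
from popsse._subjects import extract_subjects


FAST = MCMCSettings(n_burn_max=500, n_stationary=1500, seed=123)


class TestLogPosterior:
    def test_additive_over_duplicated_subject(self, small_dataset, base_truth_30):
        truth = base_truth_30
        om2 = {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl}
        etas = np.zeros((6, 3))
        etas[:, 1] = np.linspace(-0.2, 0.2, 6)
        lp1 = log_posterior(small_dataset, truth.theta, om2, truth.sigma2, etas)
        df = small_dataset.records
        extra = df[df["ID"] == 3].copy()
        extra["ID"] = 7
        bigger = p.PKDataset(records=pd.concat([df, extra], ignore_index=True), truth=truth)
        etas7 = np.vstack([etas, etas[2]])
        lp2 = log_posterior(bigger, truth.theta, om2, truth.sigma2, etas7)
        # added terms = subject 3's likelihood + eta prior (no new variance priors)
        sub = extract_subjects(small_dataset)
        from popsse.bayes import _eta_prior_rows, _loglik_rows

        ll3 = _loglik_rows(truth.theta, etas, truth.sigma2, sub)[2]
        pr3 = _eta_prior_rows(
            etas[2:3, 1:], np.array([truth.omega2_v, truth.omega2_cl])
        )[0]
        assert lp2 - lp1 == pytest.approx(ll3 + pr3, rel=1e-10)

    def test_differences_equal_fixed_effects_loglik_at_zero_eta(
        self, small_dataset, base_truth_30
    ):
        """With eta = 0 the theta-dependence is the plain Gaussian loglik."""
        truth = base_truth_30
        om2 = {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl}
        etas = np.zeros((6, 3))
        theta_b = truth.theta * np.array([1.2, 0.95, 1.05])

        def direct(theta):
            t = np.asarray(p.base_design().sampling_times)
            par = p.PopulationParameters(*theta)
            f = p.predict_concentration(par, p.SubjectEffects(), 320.0, t)
            y = small_dataset.observations["DV"].to_numpy().reshape(6, 8)
            var = truth.sigma2 * f**2
            return float(-0.5 * np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var))

        d_lp = log_posterior(
            small_dataset, theta_b, om2, truth.sigma2, etas
        ) - log_posterior(small_dataset, truth.theta, om2, truth.sigma2, etas)
        assert d_lp == pytest.approx(direct(theta_b) - direct(truth.theta), rel=1e-10)

    def test_invalid_state_rejected_with_minus_inf(self, small_dataset, base_truth_30):
        truth = base_truth_30
        om2 = {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl}
        assert log_posterior(
            small_dataset, truth.theta, om2, -0.01, np.zeros((6, 3))
        ) == -np.inf


class TestConjugateDraws:
    def test_sigma2_draws_follow_inverse_gamma(self):
        """Gibbs sigma2 draws match the stated IG(a0+N/2, b0+SS/2) law."""
        rng = np.random.default_rng(321)
        a0 = b0 = 0.01
        n_obs = 48
        ss = 0.37
        draws = (b0 + 0.5 * ss) / rng.gamma(a0 + 0.5 * n_obs, 1.0, size=10_000)
        ref = stats.invgamma(a=a0 + 0.5 * n_obs, scale=b0 + 0.5 * ss)
        ks = stats.kstest(draws, ref.cdf)
        assert ks.pvalue > 0.01

    def test_eta_posterior_matches_gaussian_closed_form(self):
        """With theta/omega2/sigma2 fixed and small IIV, the sampled eta
        posterior mean matches the linear-Gaussian closed form."""
        small = p.cv_to_omega2(0.5)
        truth = p.PopulationParameters(
            ka=2.0, v_f=40.0, cl_f=10.0, omega2_v=small, omega2_cl=small, sigma2=1e-4
        )
        design = p.base_design(n_replicates=1)
        ds = p.simulate_dataset(design, truth, 0, rng=np.random.default_rng(17))
        settings = MCMCSettings(
            n_burn_max=500, n_stationary=4000, seed=5, store_etas=True
        )
        _, chain = fit_bayes(
            ds, truth, settings, fix_omega=True, fix_theta=True, fix_sigma=True
        )
        assert chain.eta_samples is not None
        t = np.asarray(design.sampling_times)
        f0 = p.predict_concentration(truth, p.SubjectEffects(), design.dose, t)
        h = 1e-6
        G = np.empty((t.size, 2))
        for k, kw in enumerate(("eta_v", "eta_cl")):
            fp = p.predict_concentration(truth, p.SubjectEffects(**{kw: h}), design.dose, t)
            fm = p.predict_concentration(truth, p.SubjectEffects(**{kw: -h}), design.dose, t)
            G[:, k] = (fp - fm) / (2 * h)
        W = np.diag(1.0 / (truth.sigma2 * f0**2))
        A = G.T @ W @ G + np.eye(2) / small
        y = ds.observations["DV"].to_numpy().reshape(6, 8)
        for i in range(6):
            closed = np.linalg.solve(A, G.T @ W @ (y[i] - f0))
            sampled = chain.eta_samples[:, i, :].mean(axis=0)
            err = np.abs(sampled - closed)
            tol = 3 * np.array(
                [mcse(chain.eta_samples[:, i, k]) for k in range(2)]
            ) + 2e-4  # linearization slack, O(eta^2)
            assert np.all(err < tol)


class TestFitBayes:
    def test_fix_omega_holds_variances_at_initials(self, small_dataset, base_truth_30):
        res, chain = fit_bayes(small_dataset, base_truth_30, FAST, fix_omega=True)
        assert res.method == "BAYES(F)"
        assert np.all(chain.samples["omega2_v"] == base_truth_30.omega2_v)
        assert np.all(chain.samples["omega2_cl"] == base_truth_30.omega2_cl)
        assert res.covariance_success

    def test_seed_determinism(self, small_dataset, base_truth_30):
        r1, c1 = fit_bayes(small_dataset, base_truth_30, FAST)
        r2, c2 = fit_bayes(small_dataset, base_truth_30, FAST)
        assert np.array_equal(c1.samples["cl_f"], c2.samples["cl_f"])
        assert np.all(r1.theta_hat == r2.theta_hat)

    def test_posterior_means_reproducible_across_seeds(self, small_dataset, base_truth_30):
        """Independent chains agree within 3 Monte-Carlo standard errors."""
        s1 = MCMCSettings(n_burn_max=1000, n_stationary=4000, seed=11)
        s2 = MCMCSettings(n_burn_max=1000, n_stationary=4000, seed=22)
        r1, c1 = fit_bayes(small_dataset, base_truth_30, s1)
        r2, c2 = fit_bayes(small_dataset, base_truth_30, s2)
        for name in ("ka", "v_f", "cl_f"):
            se = np.hypot(mcse(c1.samples[name]), mcse(c2.samples[name]))
            assert abs(c1.samples[name].mean() - c2.samples[name].mean()) < 3 * se

    def test_bernstein_von_mises_with_many_subjects(self):
        """With 200 subjects the posterior mean approaches the truth."""
        truth = p.base_truth(30.0)
        design = p.StudyDesign(n_subjects=200, n_replicates=1)
        ds = p.simulate_dataset(design, truth, 0, rng=np.random.default_rng(44))
        res, _ = fit_bayes(ds, truth, MCMCSettings(n_burn_max=500, n_stationary=2000, seed=9))
        assert np.abs(res.theta_hat / truth.theta - 1).max() < 0.05
        assert abs(res.omega2_hat["cl_f"] / truth.omega2_cl - 1) < 0.3


class TestComposite:
    def test_chain_seeded_from_foce_estimates(self, small_dataset, base_truth_30):
        res, _ = fit_bayes_composite(
            small_dataset, base_truth_30, mcmc_settings=FAST
        )
        assert res.method == "BAYES(C)"
        stage = res.extra["foce_stage"]
        assert stage.method == "FOCE-I"
        assert not res.extra["foce_fallback_to_initials"]
        assert np.isfinite(stage.ofv)

    def test_composite_and_plain_bayes_share_stationary_distribution(
        self, small_dataset, base_truth_30
    ):
        """Same posterior regardless of initialization, within 3 MCSE."""
        s = MCMCSettings(n_burn_max=1000, n_stationary=4000, seed=77)
        _, c_b = fit_bayes(small_dataset, base_truth_30, s)
        _, c_c = fit_bayes_composite(small_dataset, base_truth_30, mcmc_settings=s)
        for name in ("ka", "v_f", "cl_f"):
            se = np.hypot(mcse(c_b.samples[name]), mcse(c_c.samples[name]))
            diff = abs(c_b.samples[name].mean() - c_c.samples[name].mean())
            assert diff < 3 * se
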