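"""FOCE-I estimator: conditional modes, objective, and full fits."""

import numpy as np
import pytest

import popsse as p
from popsse._subjects import extract_subjects
from popsse.foce import FOCESettings, conditional_mode, fit_foce, foce_objective

from _oracles import aghq_minus2ll, grid_conditional_mode


@pytest.fixture(scope="module")
def one_subject_toy():
    """Fixed single-subject dataset at 30% IIV for mode-finding checks."""
    truth = p.base_truth(30.0)
    design = p.StudyDesign(
        n_subjects=2, sampling_times=(0.5, 1.0, 4.0, 12.0), n_replicates=1
    )
    rng = np.random.default_rng(2024)
    ds = p.simulate_dataset(design, truth, 0, rng=rng)
    return ds, truth


class TestConditionalMode:
    def test_vanishing_iiv_shrinks_modes_to_zero(self, small_dataset, base_truth_30):
        eta = conditional_mode(
            small_dataset,
            base_truth_30.theta,
            {"v_f": 1e-12, "cl_f": 1e-12},
            base_truth_30.sigma2,
        )
        assert np.abs(eta).max() < 1e-4

    def test_matches_grid_search_oracle(self, one_subject_toy):
        """Newton modes agree with exhaustive 1e-3 grid search per subject."""
        ds, truth = one_subject_toy
        om2 = {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl}
        eta = conditional_mode(ds, truth.theta, om2, truth.sigma2)
        sub = extract_subjects(ds)
        for i in range(sub.n_subjects):
            times = sub.times[i][sub.mask[i]]
            y = sub.y[i][sub.mask[i]]
            ref = grid_conditional_mode(
                truth.theta,
                np.array([truth.omega2_v, truth.omega2_cl]),
                truth.sigma2,
                sub.dose[i],
                times,
                y,
            )
            assert np.abs(eta[i, 1:] - ref).max() < 2e-3

    def test_first_order_gls_consistency_in_small_eta_regime(self):
        """At small IIV/noise the mode approaches the linearized GLS solution."""
        small = p.cv_to_omega2(2.0)
        truth = p.PopulationParameters(
            ka=2.0, v_f=40.0, cl_f=10.0,
            omega2_v=small, omega2_cl=small, sigma2=1e-4,
        )
        design = p.base_design(n_replicates=1)
        ds = p.simulate_dataset(design, truth, 0, rng=np.random.default_rng(31))
        om2 = np.array([truth.omega2_v, truth.omega2_cl])
        eta = conditional_mode(ds, truth.theta, {"v_f": om2[0], "cl_f": om2[1]}, truth.sigma2)
        sub = extract_subjects(ds)
        t = np.asarray(design.sampling_times)
        f0 = p.predict_concentration(truth, p.SubjectEffects(), design.dose, t)
        # sensitivities of f to (eta_v, eta_cl) at eta = 0, by central FD
        h = 1e-6
        G = np.empty((t.size, 2))
        for k, kw in enumerate(("eta_v", "eta_cl")):
            fp = p.predict_concentration(truth, p.SubjectEffects(**{kw: h}), design.dose, t)
            fm = p.predict_concentration(truth, p.SubjectEffects(**{kw: -h}), design.dose, t)
            G[:, k] = (fp - fm) / (2 * h)
        W = np.diag(1.0 / (truth.sigma2 * f0**2))
        A = G.T @ W @ G + np.diag(1.0 / om2)
        for i in range(sub.n_subjects):
            y = sub.y[i][sub.mask[i]]
            gls = np.linalg.solve(A, G.T @ W @ (y - f0))
            # agreement to first order; the neglected terms are O(eta^2)
            assert np.abs(eta[i, 1:] - gls).max() < 1e-3


class TestObjective:
    def test_additive_over_independent_subjects(self, small_dataset, base_truth_30):
        om2 = {"v_f": base_truth_30.omega2_v, "cl_f": base_truth_30.omega2_cl}
        ofv1 = foce_objective(
            small_dataset, base_truth_30.theta, om2, base_truth_30.sigma2
        )
        df = small_dataset.records
        clone = df.copy()
        clone["ID"] = clone["ID"] + 100
        doubled = p.PKDataset(
            records=__import__("pandas").concat([df, clone], ignore_index=True),
            truth=base_truth_30,
        )
        ofv2 = foce_objective(doubled, base_truth_30.theta, om2, base_truth_30.sigma2)
        assert ofv2 == pytest.approx(2.0 * ofv1, rel=1e-10)

    def test_invariant_to_subject_relabeling_and_row_order(
        self, small_dataset, base_truth_30
    ):
        om2 = {"v_f": base_truth_30.omega2_v, "cl_f": base_truth_30.omega2_cl}
        ofv1 = foce_objective(small_dataset, base_truth_30.theta, om2, base_truth_30.sigma2)
        df = small_dataset.records.copy()
        df["ID"] = df["ID"].map({1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1})
        df = df.sample(frac=1.0, random_state=0).sort_values(["ID", "TIME"]).reset_index(drop=True)
        shuffled = p.PKDataset(records=df, truth=base_truth_30)
        ofv2 = foce_objective(shuffled, base_truth_30.theta, om2, base_truth_30.sigma2)
        assert ofv2 == pytest.approx(ofv1, rel=1e-9)

    def test_ofv_differences_match_quadrature_oracle(self, toy_dataset):
        """FOCE-I OFV differences track exact -2 log L differences within 2%."""
        ds, truth = toy_dataset
        om2 = {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl}
        theta_a = truth.theta
        theta_b = truth.theta * np.array([1.15, 0.9, 1.1])
        d_foce = foce_objective(ds, theta_b, om2, truth.sigma2) - foce_objective(
            ds, theta_a, om2, truth.sigma2
        )
        d_exact = aghq_minus2ll(ds, theta_b, om2, truth.sigma2) - aghq_minus2ll(
            ds, theta_a, om2, truth.sigma2
        )
        assert d_foce == pytest.approx(d_exact, rel=0.02)

    def test_vanishing_iiv_limit_equals_weighted_least_squares(
        self, small_dataset, base_truth_30
    ):
        """omega2 -> 0: OFV tends to the fixed-effects -2 log-likelihood."""
        truth = base_truth_30
        ofv = foce_objective(
            small_dataset, truth.theta, {"v_f": 1e-12, "cl_f": 1e-12}, truth.sigma2
        )
        t = np.asarray(p.base_design().sampling_times)
        f0 = p.predict_concentration(truth, p.SubjectEffects(), 320.0, t)
        y = small_dataset.observations["DV"].to_numpy().reshape(6, 8)
        var = truth.sigma2 * f0**2
        direct = float(np.sum(np.log(var) + (y - f0) ** 2 / var))
        # residual discrepancy is the O(omega2) term itself
        assert ofv == pytest.approx(direct, rel=1e-5)


class TestFitFOCE:
    def test_near_noiseless_limit_recovers_truth(self):
        truth = p.PopulationParameters(
            ka=2.0, v_f=40.0, cl_f=10.0, omega2_v=1e-8, omega2_cl=1e-8, sigma2=1e-8
        )
        ds = p.simulate_dataset(
            p.base_design(n_replicates=1), truth, 0, rng=np.random.default_rng(1)
        )
        fit = fit_foce(ds, truth)
        assert np.abs(fit.theta_hat / truth.theta - 1).max() < 1e-3

    def test_descent_from_true_initials(self, small_dataset, base_truth_30):
        truth = base_truth_30
        start_ofv = foce_objective(
            small_dataset,
            truth.theta,
            {"v_f": truth.omega2_v, "cl_f": truth.omega2_cl},
            truth.sigma2,
        )
        fit = fit_foce(small_dataset, truth)
        assert fit.ofv <= start_ofv + 1e-9

    def test_time_unit_rescaling_invariance(self, base_truth_30):
        """Fits in minutes vs hours give the same dimensionless estimates."""
        truth_h = base_truth_30
        ds_h = p.simulate_dataset(
            p.base_design(n_replicates=1), truth_h, 0, rng=np.random.default_rng(55)
        )
        fit_h = fit_foce(ds_h, truth_h)
        # same data with time in minutes: ka, cl scale by 1/60
        df = ds_h.records.copy()
        df["TIME"] = df["TIME"] * 60.0
        truth_min = p.PopulationParameters(
            ka=truth_h.ka / 60, v_f=truth_h.v_f, cl_f=truth_h.cl_f / 60,
            omega2_v=truth_h.omega2_v, omega2_cl=truth_h.omega2_cl,
            sigma2=truth_h.sigma2,
        )
        fit_min = fit_foce(p.PKDataset(records=df, truth=truth_min), truth_min)
        assert fit_min.theta_hat[0] * 60 == pytest.approx(fit_h.theta_hat[0], rel=1e-3)
        assert fit_min.theta_hat[1] == pytest.approx(fit_h.theta_hat[1], rel=1e-3)
        assert fit_min.theta_hat[2] * 60 == pytest.approx(fit_h.theta_hat[2], rel=1e-3)

    def test_large_dataset_consistency(self):
        """100 subjects at 30% IIV: theta within 5%, omega2 within 30%."""
        truth = p.base_truth(30.0)
        design = p.StudyDesign(n_subjects=100, n_replicates=1)
        ds = p.simulate_dataset(design, truth, 0, rng=np.random.default_rng(8))
        fit = fit_foce(ds, truth)
        assert fit.minimization_success
        assert np.abs(fit.theta_hat / truth.theta - 1).max() < 0.05
        assert abs(fit.omega2_hat["v_f"] / truth.omega2_v - 1) < 0.30
        assert abs(fit.omega2_hat["cl_f"] / truth.omega2_cl - 1) < 0.30

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            FOCESettings(sig_digits=0)
        with pytest.raises(ValueError):
            FOCESettings(inner_tol=-1.0)
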