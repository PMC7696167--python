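"""Estimation: censored likelihood, SAEM recovery, importance-sampling
likelihood against quadrature, BICc arithmetic and model ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from roscopk import units
from roscopk.estimation import (EstimationConfig, bicc, count_parameters,
                                ebe_and_shrinkage, fit_alternative_absorption,
                                individual_loglik, observed_loglik,
                                observed_loglik_fit, perturbed_init, saem_fit)
from roscopk.fastsolve import first_order_inputs, pack_params, solve_batch
from roscopk.population import ETA_FIELDS, Subject, individual_params
from roscopk.structural import TYPICAL_PARAMS
from roscopk.synthetic import TrialDesign, generate_trial


def _one_subject_frame(rows):
    """rows: list of (time, dvid, dv, cens, lloq)."""
    return pd.DataFrame([{"ID": "s1", "ARM_MG": 400.0, "TIME_H": t,
                          "DVID": dvid, "DV_NMOL_L": dv, "CENS": cens,
                          "LLOQ_NMOL_L": lloq, "HT_CM": 170.0, "PPI": 0}
                         for t, dvid, dv, cens, lloq in rows])


class TestIndividualLoglik:
    def test_censored_far_below_lloq_contributes_zero(self, final_model):
        # prediction tiny at 12 h with fast elimination: P(y < LLOQ) ~ 1
        theta = TYPICAL_PARAMS.replace(kmet=8.0, D50=100000.0)
        obs = _one_subject_frame([(12.0, 1, np.nan, 1, 14.106)])
        assert individual_loglik(obs, theta, final_model) == pytest.approx(0.0, abs=1e-6)

    def test_censored_at_prediction_equal_lloq_gives_log_half(self, final_model):
        # find the prediction at 2 h, then pretend LLOQ sits exactly there
        obs_probe = _one_subject_frame([(2.0, 1, 100.0, 0, 14.106)])
        # prediction from a zero-residual comparison: use the model curve
        batch = pack_params([TYPICAL_PARAMS])
        _, cp, _ = solve_batch(batch, np.array([units.mg_to_umol(400.0)]),
                               t_end=2.0, dt=0.05)
        f2 = cp[0, -1]
        obs = _one_subject_frame([(2.0, 1, np.nan, 1, f2)])
        assert individual_loglik(obs, TYPICAL_PARAMS, final_model) == pytest.approx(
            np.log(0.5), abs=1e-9)

    def test_uncensored_matches_hand_gaussian(self, final_model):
        batch = pack_params([TYPICAL_PARAMS])
        _, cp, _ = solve_batch(batch, np.array([units.mg_to_umol(400.0)]),
                               t_end=2.0, dt=0.05)
        f = float(cp[0, -1])
        y = f + 10.0
        obs = _one_subject_frame([(2.0, 1, y, 0, 14.106)])
        expected = norm.logpdf(y, loc=f, scale=0.297 * f)
        assert individual_loglik(obs, TYPICAL_PARAMS, final_model) == pytest.approx(
            expected, rel=1e-6)

    def test_predose_rows_ignored(self, final_model):
        obs = _one_subject_frame([(0.0, 1, np.nan, 1, 14.106)])
        assert individual_loglik(obs, TYPICAL_PARAMS, final_model) == 0.0


class TestBicc:
    def test_zero_parameters_is_minus2ll(self):
        assert bicc(123.4, 23, 276, 0, 0) == 123.4

    def test_arithmetic_example(self):
        val = bicc(100.0, 23, 276, 16, 3)
        assert val == pytest.approx(100 + 16 * np.log(23) + 3 * np.log(276),
                                    rel=1e-12)
        assert val == pytest.approx(167.03, abs=0.01)

    def test_parameter_counts(self):
        assert count_parameters("sum-ig") == (18, 7)
        assert count_parameters("fo") == (8, 6)
        assert count_parameters("fo-lag") == (8, 7)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            bicc(1.0, 0, 10, 1, 1)


class TestFirstOrderInput:
    def test_tlag_zero_reduces_to_plain_first_order(self):
        params = {"D50": np.array([1190.0])}
        t = np.linspace(0, 12, 241)
        dose = np.array([1000.0])
        ka = np.array([1.3])
        a = first_order_inputs(params, dose, t, ka, tlag=np.array([0.0]))
        b = first_order_inputs(params, dose, t, ka, tlag=None)
        np.testing.assert_allclose(a[0], b[0])
        np.testing.assert_allclose(a[1], b[1])

    def test_fast_ka_approximates_bolus_auc(self):
        # complete first-order absorption leaves AUC(0-inf) equal to the
        # bolus value; fast ka makes the shape bolus-like (the step must
        # resolve the 1/ka input time constant)
        batch = pack_params([TYPICAL_PARAMS])
        dose = np.array([units.mg_to_umol(400.0)])
        grid, cp, cm = solve_batch(batch, dose, t_end=120.0, dt=0.005,
                                   absorption="fo", ka=np.array([50.0]))
        auc_p = np.trapezoid(cp[0], grid)
        fr = dose[0] / (dose[0] + TYPICAL_PARAMS.D50)
        bolus = fr * dose[0] * 1000.0 / (TYPICAL_PARAMS.kmet * TYPICAL_PARAMS.V)
        assert auc_p == pytest.approx(bolus, rel=0.01)


class TestObservedLoglik:
    def test_zero_omega_equals_plain_likelihood(self, final_model):
        m0 = final_model.replace(omega=(0.0,) * 7, corr_T1max_CV2=0.0,
                                 corr_dT2max_CV1=0.0)
        ds = generate_trial(m0, TrialDesign(arms={400: 3}), seed=2)
        m2ll, se = observed_loglik(ds, m0, seed=1)
        assert se == 0.0
        total = 0.0
        for sid, sub in ds.obs.groupby("ID"):
            theta = individual_params(
                m0, Subject(id=str(sid), dose_mg=400.0,
                            height_cm=float(sub["HT_CM"].iloc[0]),
                            ppi=bool(sub["PPI"].iloc[0])), np.zeros(7))
            total += individual_loglik(sub, theta, m0)
        assert m2ll == pytest.approx(-2.0 * total, rel=1e-9)

    def test_matches_1d_quadrature_oracle(self, final_model):
        """With variability on V only, the marginal likelihood is a 1-D
        integral computable by adaptive quadrature."""
        omega_v = 0.5
        om = [0.0] * 7
        om[ETA_FIELDS.index("V")] = omega_v
        m = final_model.replace(omega=tuple(om), corr_T1max_CV2=0.0,
                                corr_dT2max_CV1=0.0)
        ds = generate_trial(m, TrialDesign(arms={400: 1}), seed=4)
        sub = ds.obs
        s = Subject(id=str(ds.subjects["ID"].iloc[0]), dose_mg=400.0,
                    height_cm=float(ds.subjects["HT_CM"].iloc[0]),
                    ppi=bool(ds.subjects["PPI"].iloc[0]))

        def integrand(eta_v):
            eta = np.zeros(7)
            eta[ETA_FIELDS.index("V")] = eta_v
            ll = individual_loglik(sub, individual_params(m, s, eta), m)
            return np.exp(ll) * norm.pdf(eta_v, scale=omega_v)

        integral, _ = quad(integrand, -4 * omega_v, 4 * omega_v, limit=200)
        oracle = -2.0 * np.log(integral)
        m2ll, se = observed_loglik(ds, m, n_is=2000, seed=3)
        assert m2ll == pytest.approx(oracle, abs=max(3 * se, 0.5))

    def test_stable_under_doubling_n_is(self, final_model, study_trial):
        a, se_a = observed_loglik(study_trial, final_model, n_is=500, seed=1)
        b, se_b = observed_loglik(study_trial, final_model, n_is=1000, seed=2)
        assert abs(a - b) < 3.0 * np.hypot(se_a, se_b) + 1.0


class TestSaemRecovery:
    def test_noiseless_dense_design_converges_toward_truth(self, final_model):
        """Zero residual error, zero IIV, dense 0.2 h sampling: SAEM from a
        20%-perturbed start must approach the generating typical values and
        drive the residual SD to (near) zero."""
        quiet = final_model.replace(
            omega=(0.0,) * 7, corr_T1max_CV2=0.0, corr_dT2max_CV1=0.0,
            err_parent_b=0.0, err_met_a=0.0, err_met_b=0.0,
            beta_ppi_T1max=0.0, beta_height_V=0.0)
        times = tuple(np.round(np.arange(0.0, 12.01, 0.2), 2))
        ds = generate_trial(quiet, TrialDesign(arms={200: 2, 400: 2, 800: 2},
                                               nominal_times=times), seed=1)
        init = perturbed_init(final_model, 2, scale=0.2)
        fit = saem_fit(ds, init, EstimationConfig(
            n_explore=300, n_smooth=300, seed=4,
            estimate_covariates=False, estimate_correlations=False))
        truth = {"D50": 1190, "T1max": 0.676, "dT2max": 1.04, "CV1": 0.542,
                 "CV2": 0.354, "V": 62.2, "ke": 2.58, "pi1": 0.285,
                 "k12": 1.82, "k21": 0.768, "kmet": 2.07}
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=0.15), k
        assert fit.params["b1"] < 0.02

    def test_censoring_consistency(self, final_model):
        """Fitting data with LLOQ censoring applied vs the same data fully
        observed gives compatible headline estimates."""
        lo = TrialDesign(lloq_ng_ml=1e-6)
        ds_full = generate_trial(final_model, lo, seed=6)
        obs = ds_full.obs.copy()
        cens_mask = (obs["DV_NMOL_L"] < np.where(obs["DVID"] == 1, 14.106, 13.571)
                     ) & (obs["TIME_H"] > 0)
        obs.loc[cens_mask, "CENS"] = 1
        obs.loc[cens_mask, "DV_NMOL_L"] = np.nan
        obs.loc[cens_mask, "LLOQ_NMOL_L"] = np.where(
            obs.loc[cens_mask, "DVID"] == 1, 14.106, 13.571)
        from roscopk.synthetic import PKDataset
        ds_cens = PKDataset(obs=obs, subjects=ds_full.subjects)
        cfg = EstimationConfig(n_explore=150, n_smooth=75, seed=8)
        init = perturbed_init(final_model, 5)
        fit_full = saem_fit(ds_full, init, cfg)
        fit_cens = saem_fit(ds_cens, init, cfg)
        for k in ("D50", "V", "kmet", "ke"):
            assert fit_cens.params[k] == pytest.approx(fit_full.params[k],
                                                       rel=0.20), k


class TestModelSelection:
    def test_bicc_prefers_generating_absorption_model(self, final_model):
        """On data generated with the sum-of-inverse-Gaussian input, BICc
        ranks sum-IG best and the lagged first-order model above the plain
        one in at least 2 of 3 seeds."""
        n_obs_key = lambda ds: int((ds.obs["TIME_H"] > 0).sum())
        cfg = dict(n_explore=120, n_smooth=60)
        wins_sig, wins_lag = 0, 0
        for seed in (1, 2, 3):
            ds = generate_trial(final_model, TrialDesign(), seed=seed)
            init = perturbed_init(final_model, seed)
            fit_sig = saem_fit(ds, init, EstimationConfig(seed=seed, **cfg))
            fit_fo = fit_alternative_absorption(
                ds, "fo", init, EstimationConfig(seed=seed, **cfg))
            fit_lag = fit_alternative_absorption(
                ds, "fo-lag", init, EstimationConfig(seed=seed, **cfg))
            n_obs = n_obs_key(ds)
            bic = {}
            for name, fit in (("sum-ig", fit_sig), ("fo", fit_fo),
                              ("fo-lag", fit_lag)):
                m2ll, _ = observed_loglik_fit(ds, fit, n_is=500, seed=seed)
                bic[name] = bicc(m2ll, ds.n_subjects, n_obs,
                                 *count_parameters(name))
            wins_sig += bic["sum-ig"] < min(bic["fo"], bic["fo-lag"])
            wins_lag += bic["fo-lag"] < bic["fo"]
        assert wins_sig >= 2
        assert wins_lag >= 2


class TestEbe:
    def test_subject_without_observations_gets_prior_mode(self, final_model,
                                                          study_trial):
        from roscopk.synthetic import PKDataset
        obs = study_trial.obs
        keep = obs["ID"] != "S001"
        ds = PKDataset(obs=obs[keep].reset_index(drop=True),
                       subjects=study_trial.subjects)
        ebe, _, _ = ebe_and_shrinkage(ds, final_model)
        row = ebe[ebe["ID"] == "S001"].iloc[0]
        assert all(row[f"eta_{f}"] == 0.0 for f in ETA_FIELDS)

    def test_low_noise_data_recovers_true_etas(self, final_model):
        quiet = final_model.replace(err_parent_b=0.02, err_met_a=0.2,
                                    err_met_b=0.02)
        times = tuple(np.round(np.arange(0.0, 12.01, 0.5), 2))
        ds = generate_trial(quiet, TrialDesign(arms={400: 6},
                                               nominal_times=times), seed=9)
        ebe, eta_shr, eps_shr = ebe_and_shrinkage(ds, quiet)
        truth = ds.truth.set_index("ID")
        for f in ("D50", "V", "ke"):
            est = ebe.set_index("ID")[f"eta_{f}"]
            np.testing.assert_allclose(est, truth[f"eta_{f}"][est.index],
                                       atol=0.08)
        # rich, nearly noiseless data: no shrinkage relative to the realized
        # etas (1 - SD(eta_hat)/omega itself is pure SD sampling noise at
        # n = 6, so compare the estimated spread with the true one)
        for f in ("D50", "V", "ke"):
            est_sd = np.std(ebe[f"eta_{f}"], ddof=1)
            true_sd = np.std(truth[f"eta_{f}"], ddof=1)
            assert est_sd == pytest.approx(true_sd, rel=0.15), f
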