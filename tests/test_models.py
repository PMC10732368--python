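"""Encoding-model fitting, BIC comparison and generalization predictions."""

import warnings

import numpy as np
import pytest

import bimanual_adapt as ba

B = 13.0


def _stacked(noise_free_conditions, encoder):
    Fs, vls, vrs = [], [], []
    for vl, vr in noise_free_conditions.values():
        Fs.append(encoder(vl, vr))
        vls.append(vl)
        vrs.append(vr)
    return tuple(map(np.concatenate, (Fs, vls, vrs)))


class TestFitEncodingModel:
    def test_recovers_average_encoding(self, noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * 0.5 * (vl + vr))
        fit = ba.fit_encoding_model("weighted", F, vl, vr)
        assert fit.omega == pytest.approx(0.5, abs=1e-6)
        assert fit.alpha == pytest.approx(0.8, abs=1e-6)
        assert fit.k_params == 2

    def test_recovers_pure_right_encoding(self, noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        fit = ba.fit_encoding_model("weighted", F, vl, vr)
        assert fit.omega == pytest.approx(1.0, abs=1e-6)

    def test_single_gain_models_are_exact_projections(self,
                                                      noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.6 * B * vl)
        fit = ba.fit_encoding_model("left", F, vl, vr)
        assert fit.alpha == pytest.approx(0.6, abs=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-16)
        assert fit.omega is None and fit.k_params == 1

    def test_weighted_matches_two_regressor_lstsq_oracle(self, rng):
        """Independent oracle: the weighted model is linear in
        (alpha*omega, alpha*(1-omega)); lstsq on [v_r, v_l] gives the
        global optimum."""
        v = ba.generate_velocity_profile("slow")
        vl = np.pad(v, (20, 0))
        vr = np.pad(ba.generate_velocity_profile("fast"), (0, 20))
        F = 0.75 * B * (0.3 * vr + 0.7 * vl) + rng.normal(0, 0.2, vl.shape)
        fit = ba.fit_encoding_model("weighted", F, vl, vr)
        X = np.column_stack([B * vr, B * vl])
        beta = np.linalg.lstsq(X, F, rcond=None)[0]
        alpha = beta.sum()
        omega = beta[0] / alpha
        assert fit.alpha == pytest.approx(alpha, abs=1e-8)
        assert fit.omega == pytest.approx(omega, abs=1e-8)

    def test_weighted_matches_grid_search_oracle(self, noise_free_conditions):
        """Exhaustive grid (alpha 0..2, omega -0.5..1.5, step 0.001)
        agrees with the nonlinear fit within one grid step."""
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * (0.65 * vr + 0.35 * vl))
        fit = ba.fit_encoding_model("weighted", F, vl, vr)
        alphas = np.arange(0.0, 2.0005, 0.001)
        omegas = np.arange(-0.5, 1.5005, 0.001)
        D, Q = B * (vr - vl), B * vl
        A, O = np.meshgrid(alphas, omegas, indexing="ij")
        sse = (F @ F - 2 * A * O * (F @ D) - 2 * A * (F @ Q)
               + A**2 * O**2 * (D @ D) + 2 * A**2 * O * (D @ Q)
               + A**2 * (Q @ Q))
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert abs(fit.alpha - alphas[i]) <= 0.001
        assert abs(fit.omega - omegas[j]) <= 0.001

    def test_identical_velocities_collapse_all_models(self):
        """With v_left == v_right the four parametric models coincide:
        identical SSE, and the omega-identifiability warning fires."""
        v = ba.generate_velocity_profile("medium")
        F = 0.9 * B * v
        with pytest.warns(ba.OmegaIdentifiabilityWarning):
            fits = ba.fit_all_models(F, v, v.copy())
        sses = [f.sse for f in fits.values()]
        assert max(sses) - min(sses) <= 1e-12
        assert not fits["weighted"].omega_identifiable

    def test_distinct_velocities_are_identifiable(self, noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ba.OmegaIdentifiabilityWarning)
            fit = ba.fit_encoding_model("weighted", F, vl, vr)
        assert fit.omega_identifiable

    def test_weighted_sse_never_exceeds_single_gain_models(self, rng):
        """The weighted model nests right, left and average."""
        vl = ba.generate_velocity_profile("medium")
        vr = ba.generate_velocity_profile("fast")[:len(vl)]
        F = rng.normal(0, 1, vl.shape)  # arbitrary data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ba.OmegaIdentifiabilityWarning)
            fits = ba.fit_all_models(F, vl, vr)
        assert fits["weighted"].sse <= min(
            fits[m].sse for m in ("right", "left", "average")) + 1e-9

    def test_r2_at_most_one(self, noise_free_conditions, rng):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        F = F + rng.normal(0, 0.3, F.shape)
        for fit in ba.fit_all_models(F, vl, vr).values():
            assert fit.r2 <= 1.0


class TestNonparametricReference:
    def test_mean_alpha_of_constant_fits(self, noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        fits = [ba.fit_encoding_model("right", F, vl, vr)] * 3
        ref = ba.nonparametric_reference(fits, F, vl, vr)
        assert ref.alpha == pytest.approx(0.8)
        assert ref.k_params == 0

    def test_override_uses_published_constant(self, noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        ref = ba.nonparametric_reference([], F, vl, vr,
                                         alpha_override=ba.REFERENCE_ALPHA)
        assert ref.alpha == 0.822

    def test_reference_sse_at_least_best_parametric(self, rng,
                                                    noise_free_conditions):
        F, vl, vr = _stacked(noise_free_conditions,
                             lambda vl, vr: 0.8 * B * vr)
        F = F + rng.normal(0, 0.3, F.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = ba.fit_all_models(F, vl, vr)
        ref = ba.nonparametric_reference(fits.values(), F, vl, vr)
        assert ref.sse >= min(f.sse for f in fits.values())

    def test_empty_fit_set_rejected(self):
        with pytest.raises(ValueError):
            ba.nonparametric_reference([], np.ones(10), np.ones(10),
                                       np.ones(10))


class TestBIC:
    def test_parameter_penalty_is_log_n(self):
        n, sse = 800, 12.0
        assert (ba.compute_bic(sse, n, 2) - ba.compute_bic(sse, n, 1)
                == pytest.approx(np.log(800)))

    def test_halving_sse_drops_bic_by_n_log_2(self):
        n = 500
        assert (ba.compute_bic(10.0, n, 1) - ba.compute_bic(5.0, n, 1)
                == pytest.approx(n * np.log(2)))

    def test_zero_parameter_term_vanishes(self):
        assert ba.compute_bic(7.0, 100, 0) == pytest.approx(
            100 * np.log(7.0 / 100))

    def test_degenerate_sse_rejected(self):
        with pytest.raises(ValueError):
            ba.compute_bic(0.0, 100, 1)
        with pytest.raises(ValueError):
            ba.compute_bic(1.0, 1, 1)


def _cond_profile(label, alpha=0.8, omega=None, encoder=None):
    cond = ba.CONDITIONS[label]
    vl = ba.generate_velocity_profile(cond.left)
    vr = (ba.generate_velocity_profile(cond.right) if cond.bimanual
          else np.zeros_like(vl))
    n = max(len(vl), len(vr))
    vl = np.pad(vl, (0, n - len(vl)))
    vr = np.pad(vr, (0, n - len(vr)))
    F = encoder(vl, vr) if encoder else np.zeros(n)
    return ba.AlignedForceProfile(
        force=F, left_speed=vl, right_speed=vr,
        padded=np.zeros(n, dtype=bool),
        reference_hand="right" if cond.bimanual else "left",
        center_ms=0.0, condition=label)


class TestGeneralizationPredictions:
    @pytest.fixture(scope="class")
    def cond_profiles(self):
        return {lab: _cond_profile(lab) for lab in ba.CONDITIONS}

    def test_right_encoding_predicts_silence_on_unimanual(self, cond_profiles):
        fit = ba.EncodingModelFit("right", 0.8, None, 1.0, 100, 1,
                                  np.nan, 1.0)
        preds = ba.predict_generalization(fit, cond_profiles)
        for lab in ("u_s", "u_m", "u_f"):
            assert not np.any(preds[lab].force)
            assert preds[lab].fc_percent is None

    def test_average_encoding_unimanual_peak_is_half_of_bimanual(
            self, cond_profiles):
        fit = ba.EncodingModelFit("average", 0.8, None, 1.0, 100, 1,
                                  np.nan, 1.0)
        preds = ba.predict_generalization(fit, cond_profiles)
        ratio = preds["u_m"].peak_force / preds["b_mm"].peak_force
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_in_sample_prediction_reproduces_fitted_forces(self):
        profiles = {lab: _cond_profile(
            lab, encoder=lambda vl, vr: 0.8 * B * (0.6 * vr + 0.4 * vl))
            for lab in ("b_sf", "b_mm", "b_fs")}
        F, vl, vr = ba.stack_profiles(list(profiles.values()))
        fit = ba.fit_encoding_model("weighted", F, vl, vr)
        preds = ba.predict_generalization(fit, profiles)
        for lab, prof in profiles.items():
            np.testing.assert_allclose(preds[lab].force, prof.force,
                                       atol=1e-8)

    def test_missing_condition_skipped_with_warning(self):
        fit = ba.EncodingModelFit("right", 0.8, None, 1.0, 100, 1,
                                  np.nan, 1.0)
        with pytest.warns(UserWarning, match="no velocity profiles"):
            preds = ba.predict_generalization(fit, {"b_mm":
                                                    _cond_profile("b_mm")})
        assert set(preds) == {"b_mm"}


class TestPredictionMSE:
    def test_perfect_prediction_is_zero(self):
        obs = {"b_ss": 70.0, "b_sm": 75.0}
        assert ba.prediction_mse(obs, obs) == 0.0

    def test_constant_offset_squares(self):
        obs = {"b_ss": 70.0, "b_sm": 75.0, "b_sf": 80.0}
        pred = {k: v + 3.0 for k, v in obs.items()}
        assert ba.prediction_mse(pred, obs) == pytest.approx(9.0)

    def test_matches_hand_computed_table(self):
        # hand-worked: ((82-80)^2 + (66-70)^2) / 2 = 10, excluding b_mm
        pred = {"b_mm": 75.0, "b_sf": 82.0, "b_fs": 66.0}
        obs = {"b_mm": 50.0, "b_sf": 80.0, "b_fs": 70.0}
        got = ba.prediction_mse(pred, obs, exclude=("b_mm",))
        assert got == pytest.approx(10.0)

    def test_disjoint_conditions_rejected(self):
        with pytest.raises(ValueError):
            ba.prediction_mse({"b_ss": 1.0}, {"b_ff": 1.0})


class TestWeightTrajectory:
    @pytest.mark.parametrize("omega_true", [1.0, 0.5])
    def test_constant_weight_recovered_in_every_window(self, omega_true):
        # learner starts at its asymptotic gain so every 96-trial window
        # sees a constant (alpha, omega) ground truth
        learner = ba.LearnerConfig(omega=omega_true, alpha0=0.8,
                                   execution_noise_sd=0.05,
                                   force_drift_sd=0.0)
        trials = ba.simulate_participant("evident", 1, seed=3,
                                         learner=learner)
        profiles = ba.extract_clamp_profiles(trials)
        traj = ba.fit_weight_trajectory(profiles)
        good = traj[~traj["missing"]]
        assert len(good) == 20
        np.testing.assert_allclose(good["omega"], omega_true, atol=0.05)

    def test_no_profiles_rejected(self):
        with pytest.raises(ValueError):
            ba.fit_weight_trajectory([])
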