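import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitbalance import balance_metrics as bm
from gaitbalance.detection_eval import StepPool, metric_from_pool
from gaitbalance.pipeline import group_step_pool
from gaitbalance.validation import chi2_sd_band, sigma_recovery_run


def steps_frame(widths, times=None, sides=None, t0=2.0, dt=0.55):
    n = len(widths)
    times = np.full(n, dt) if times is None else np.asarray(times, float)
    sides = np.tile(["left", "right"], n)[:n] if sides is None else sides
    return pd.DataFrame({
        "time_s": t0 + np.arange(n) * dt,
        "side": sides,
        "width_m": widths,
        "step_time_s": times,
        "placement_m": np.asarray(widths, float),
        "com_rel_pos_m": np.zeros(n),
        "com_vel_mps": np.zeros(n),
        "midstance_s": t0 + np.arange(n) * dt - 0.2,
    })


class TestStepSeries:
    def test_sign_convention_uncrossed_and_crossed(self):
        n, rate = 800, 100.0
        time = np.arange(n) / rate
        markers = {
            "L_calcaneus": np.tile([0.3, 0.10, 0.02], (n, 1)),
            "R_calcaneus": np.tile([-0.2, -0.10, 0.02], (n, 1)),
        }
        events = pd.DataFrame([
            {"time_s": 2.0, "type": "heel_strike", "side": "right",
             "source": "cop", "valid": True, "reason": "none"},
            {"time_s": 2.55, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"},
        ])
        steps = bm.compute_step_series(events, markers, time, prefiltered=True)
        assert steps["width_m"].iloc[0] == pytest.approx(0.20, abs=1e-9)
        # crossed configuration: right foot to the left of the left foot
        markers["R_calcaneus"] = np.tile([-0.2, 0.15, 0.02], (n, 1))
        steps = bm.compute_step_series(events, markers, time, prefiltered=True)
        assert steps["width_m"].iloc[0] == pytest.approx(-0.05, abs=1e-9)

    def test_pipeline_mean_width_within_3_se(self, steady_trial_pair,
                                             subject_params):
        pool = group_step_pool(steady_trial_pair, "steady")
        se = subject_params.step_width_sd / np.sqrt(len(pool.widths))
        assert abs(pool.widths.mean() - subject_params.mean_step_width) < 3 * se


class TestVariabilityMetrics:
    def test_constant_widths_give_zero(self):
        steps = steps_frame(np.full(600, 0.12))
        assert bm.step_width_variability(steps).value == pytest.approx(0.0, abs=1e-12)

    def test_budget_rule_uses_first_570_of_700(self):
        rng = np.random.default_rng(0)
        w = rng.normal(0.12, 0.02, 700)
        score = bm.step_width_variability(steps_frame(w))
        assert score.n_used == 570
        assert score.value == pytest.approx(np.std(w[:570], ddof=1))

    def test_shortfall_raises_named_error(self):
        steps = steps_frame(np.full(500, 0.12))
        with pytest.raises(bm.ShortfallError, match="budget"):
            bm.step_width_variability(steps, subject="S01", condition="jets")

    def test_gaussian_width_sd_within_sampling_band(self, rng):
        sd = 0.015
        w = rng.normal(0.12, sd, 570)
        lo, hi = chi2_sd_band(sd, 570)
        assert lo <= bm.step_width_variability(steps_frame(w)).value <= hi

    def test_per_side_demeaning_removes_asymmetry(self):
        times = np.tile([0.60, 0.50], 300)[:600]
        steps = steps_frame(np.full(600, 0.1), times=times)
        assert bm.step_time_variability(steps).value == pytest.approx(0.0, abs=1e-12)

    def test_step_time_matches_brute_force_oracle(self, rng):
        times = rng.normal(0.55, 0.02, 570)
        sides = rng.choice(["left", "right"], 570)
        steps = steps_frame(np.full(570, 0.1), times=times, sides=sides)
        got = bm.step_time_variability(steps).value
        # independent oracle: demean each side, concatenate, SD
        parts = [times[sides == s] - times[sides == s].mean()
                 for s in ("left", "right")]
        expect = np.std(np.concatenate(parts), ddof=1)
        assert got == pytest.approx(expect, rel=1e-12)

    @given(offset=st.floats(-0.5, 0.5), scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_location_invariance_and_scale_equivariance(self, offset, scale):
        rng = np.random.default_rng(99)
        w = rng.normal(0.12, 0.015, 570)
        base = bm.step_width_variability(steps_frame(w)).value
        shifted = bm.step_width_variability(steps_frame(w + offset)).value
        scaled = bm.step_width_variability(steps_frame(w * scale)).value
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestFootPlacementModel:
    def test_noiseless_law_recovered_exactly(self, rng):
        pos = rng.normal(0.05, 0.01, 570)
        vel = rng.normal(0.2, 0.05, 570)
        y = 0.01 + 1.2 * pos + 0.3 * vel
        coef, sd = bm.fit_foot_placement_model(pos, vel, y)
        np.testing.assert_allclose(coef, [0.01, 1.2, 0.3], atol=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_law_residual_sd_in_band(self, rng):
        pos = rng.normal(0.05, 0.01, 570)
        vel = rng.normal(0.2, 0.05, 570)
        sigma = 0.009
        y = 1.2 * pos + 0.3 * vel + rng.normal(0, sigma, 570)
        _, sd = bm.fit_foot_placement_model(pos, vel, y)
        lo, hi = chi2_sd_band(sigma, 570, n_params=3)
        assert lo <= sd <= hi

    def test_rank_deficient_inputs_rejected(self):
        pos = np.full(570, 0.05)
        vel = np.full(570, 0.2)
        with pytest.raises(ValueError, match="rank"):
            bm.fit_foot_placement_model(pos, vel, np.ones(570))

    def test_distinct_laws_give_distinct_models(self, rng):
        pos = rng.normal(0.05, 0.01, 570)
        vel = rng.normal(0.2, 0.05, 570)
        c1, _ = bm.fit_foot_placement_model(pos, vel, 1.2 * pos + 0.3 * vel)
        c2, _ = bm.fit_foot_placement_model(pos, vel, 0.8 * pos + 0.5 * vel)
        assert not np.allclose(c1, c2)

    def test_predictability_bounded_by_placement_sd(self, steady_trial_pair):
        # regression residual SD cannot exceed the outcome SD on the same steps
        pool = group_step_pool(steady_trial_pair, "steady")
        resid = metric_from_pool(pool, "foot_placement_predictability")
        outcome_sd = np.std(pool.placements - pool.placements.mean(), ddof=1)
        # placements pool left and right steps (bimodal), compare per metric spirit:
        width_dir_sd = np.std(pool.widths, ddof=1)
        assert resid <= max(outcome_sd, width_dir_sd) + 1e-12

    def test_sigma_recovery_through_full_pipeline(self):
        run = sigma_recovery_run(seed=77)
        for name, n_params in (("step_width_sd", 1), ("step_time_sd", 2),
                               ("placement_sd", 3)):
            est, true = run[name]
            lo, hi = chi2_sd_band(true, 570, n_params=n_params)
            assert lo <= est <= hi, name


class TestStrideNormalizationAndEmbedding:
    def test_constant_signal_normalizes_to_constant(self):
        t = np.arange(0, 10, 0.01)
        x = np.full((len(t), 3), 2.5)
        stack = bm.time_normalize_strides(x, t, [(1.0, 2.1), (2.1, 3.3)])
        assert stack.shape == (2, 100, 3)
        assert np.allclose(stack, 2.5)

    def test_linear_signal_keeps_endpoints(self):
        t = np.arange(0, 10, 0.01)
        x = 3.0 * t
        stack = bm.time_normalize_strides(x, t, [(2.0, 3.1)])
        assert stack[0, 0, 0] == pytest.approx(6.0, abs=1e-6)
        assert stack[0, -1, 0] == pytest.approx(9.3, abs=1e-6)
        assert np.allclose(np.diff(stack[0, :, 0]), np.diff(stack[0, :, 0])[0],
                           atol=1e-9)

    def test_144_strides_give_144x100_stack(self):
        t = np.arange(0, 200, 0.01)
        bounds = [(2.0 + 1.1 * k, 2.0 + 1.1 * (k + 1)) for k in range(144)]
        stack = bm.time_normalize_strides(np.sin(t), t, bounds)
        assert stack.shape == (144, 100, 1)

    def test_too_short_stride_rejected(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(ValueError, match="shorter"):
            bm.time_normalize_strides(np.sin(t), t, [(1.0, 1.015)])

    def test_embedding_dimension_is_channels_times_copies(self, rng):
        stack = rng.normal(size=(6, 100, 3))
        emb = bm.delay_embed(stack)
        assert emb.dimension == 15
        assert emb.values.shape[1] == 3 * 5

    def test_identity_embedding_with_single_copy(self, rng):
        stack = rng.normal(size=(3, 100, 3))
        emb = bm.delay_embed(stack, copies=1, delay=10)
        np.testing.assert_array_equal(emb.values, stack.reshape(-1, 3))

    def test_embedded_length_per_segment(self, rng):
        stack = rng.normal(size=(9, 100, 3))
        emb = bm.delay_embed(stack, np.zeros(9, dtype=int))
        assert emb.segment_length[0] == 900 - 4 * 10

    def test_insufficient_lookahead_rejected(self, rng):
        stack = rng.normal(size=(1, 30, 3))
        with pytest.raises(ValueError, match="lookahead"):
            bm.delay_embed(stack, copies=5, delay=10)


class TestMarginOfStability:
    def test_closed_form_extrapolation_offset(self):
        # l = 1 m -> omega0 = 3.132 1/s; v = 0.3132 m/s shifts the xCoM 0.100 m
        w0 = bm.pendulum_natural_frequency(1.0)
        assert w0 == pytest.approx(3.132, abs=1e-3)
        x = bm.extrapolated_com(np.zeros(3), np.array([0.0, 0.3132, 0.0]), 1.0)
        assert x[1] == pytest.approx(0.100, abs=5e-4)

    def test_static_limit_equals_marker_distance(self):
        n, rate = 64000, 100.0
        time = np.arange(n) / rate
        markers = {
            "L_ankle": np.tile([0.0, 0.10, 0.07], (n, 1)),
            "R_ankle": np.tile([0.0, -0.10, 0.07], (n, 1)),
            "L_metatarsal5": np.tile([0.15, 0.13, 0.02], (n, 1)),
            "R_metatarsal5": np.tile([0.15, -0.13, 0.02], (n, 1)),
        }
        com = bm.ComState(position=np.tile([0.0, 0.0, 1.0], (n, 1)),
                          velocity=np.zeros((n, 3)), time=time)
        hs_times = 2.0 + 0.55 * np.arange(570)
        sides = np.tile(["left", "right"], 285)
        score = bm.margin_of_stability(com, markers, time, events=None,
                                       heel_strike_times=hs_times, sides=sides,
                                       prefiltered=True)
        assert score.value == pytest.approx(0.13, abs=1e-9)
        assert score.n_used == 570

    def test_shortfall_rejected(self):
        n, rate = 1000, 100.0
        time = np.arange(n) / rate
        markers = {k: np.zeros((n, 3)) for k in
                   ("L_ankle", "R_ankle", "L_metatarsal5", "R_metatarsal5")}
        com = bm.ComState(position=np.zeros((n, 3)), velocity=np.zeros((n, 3)),
                          time=time)
        with pytest.raises(bm.ShortfallError):
            bm.margin_of_stability(com, markers, time, events=None,
                                   heel_strike_times=np.array([2.0, 2.5]),
                                   sides=np.array(["left", "right"]),
                                   prefiltered=True)


class TestComDisplacement:
    def test_generator_shift_recovered(self, perturbed_trial, perturbed_events):
        from gaitbalance.signal_io import estimate_com
        trial = perturbed_trial.trial
        com = estimate_com(trial.pelvis_markers(), trial.marker_rate,
                           time=trial.marker_time)
        truth = perturbed_trial.truth
        score = bm.com_displacement(com, perturbed_events, truth.perturbations)
        gt = truth.com_displacements
        qual = gt[(gt["direction"] == "right") & (gt["magnitude_pct_bw"] == 7.5)]
        assert score.n_used == 2
        assert score.value == pytest.approx(qual["projected_m"].mean(), abs=0.003)

    def test_fewer_than_two_qualifying_rejected(self, steady_com):
        log = pd.DataFrame([{"onset_s": 30.0, "direction": "right",
                             "magnitude_pct_bw": 7.5, "duration_s": 0.3}])
        with pytest.raises(ValueError, match="two qualifying"):
            bm.com_displacement(steady_com, pd.DataFrame(), log)


class TestRegimeSelection:
    def test_windows_and_counts(self, perturbed_trial, perturbed_events,
                                 steady_trial):
        from gaitbalance.balance_metrics import trial_step_series
        pert_steps = trial_step_series(perturbed_trial.trial, perturbed_events)
        log = perturbed_trial.truth.perturbations
        onsets = np.sort(log["onset_s"].to_numpy())

        steady = bm.select_regime(pert_steps, log, "steady")
        for t in steady["time_s"]:
            lags = t - onsets
            prev = lags[lags > 0]
            assert len(prev) and 18.0 < prev.min() <= 23.0

        post = bm.select_regime(pert_steps, log, "perturbation_only")
        for t in post["time_s"]:
            lags = t - onsets
            prev = lags[lags > 0]
            assert len(prev) and prev.min() <= 7.0
        # ~1.8 steps/s for 7 s after each of 16 onsets
        assert 150 <= len(post) <= 250

    def test_zero_perturbations_give_empty_post_selection(self, steady_trial):
        steps = bm.trial_step_series(steady_trial.trial)
        steps["trial_kind"] = "perturbed"
        out = bm.select_regime(steps, None, "perturbation_only")
        assert len(out) == 0

    def test_unknown_regime_rejected(self, steady_trial):
        steps = bm.trial_step_series(steady_trial.trial)
        with pytest.raises(ValueError, match="regime"):
            bm.select_regime(steps, None, "bogus")
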