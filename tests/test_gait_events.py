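import numpy as np
import pandas as pd
import pytest

from gaitbalance.gait_events import (
    detect_events_force,
    detect_heel_strikes_cop,
    exclude_stutter_steps,
    find_midstance,
    merge_event_tables,
    valid_heel_strikes,
)
from gaitbalance.validation import heel_strike_oracle_run


class TestCopHeelStrikes:
    def test_oracle_equivalence_on_steady_walking(self):
        res = heel_strike_oracle_run(seed=41, duration=90.0)
        assert res.recall >= 0.99
        assert res.precision >= 0.99
        assert res.max_abs_error_s <= 0.010

    def test_pairing_window_keeps_earlier_candidate(self):
        # one genuine fore-aft crossing and one ML crossing 40 ms later must
        # collapse to a single event at the earlier time
        rate = 1000.0
        t = np.arange(0, 4, 1 / rate)
        cop_x = -0.5 * t + 0.6 / (1 + np.exp(-(t - 2.0) / 0.02))
        cop_y = 0.15 / (1 + np.exp(-(t - 2.04) / 0.02))
        ev = detect_heel_strikes_cop(cop_x, cop_y, rate, "steady")
        assert len(ev) == 1
        assert ev["time_s"].iloc[0] < 2.04

    def test_window_length_depends_on_trial_kind(self):
        # two fore-aft candidates 170 ms apart: merged in steady walking
        # (200 ms window), kept separate in perturbed trials (150 ms window)
        rate = 1000.0
        t = np.arange(0, 4, 1 / rate)
        cop_x = (-0.5 * t + 0.4 / (1 + np.exp(-(t - 2.0) / 0.01))
                 + 0.4 / (1 + np.exp(-(t - 2.17) / 0.01)))
        cop_y = np.zeros_like(t)
        steady = detect_heel_strikes_cop(cop_x, cop_y, rate, "steady")
        perturbed = detect_heel_strikes_cop(cop_x, cop_y, rate, "perturbed")
        assert len(steady) == 1
        assert len(perturbed) == 2

    def test_sides_assigned_from_ml_transfer_direction(self, steady_trial,
                                                       steady_events):
        hs = valid_heel_strikes(steady_events)
        truth = steady_trial.truth
        det = hs["time_s"].to_numpy()
        agree = []
        for t, side in zip(truth.heel_strike_times[1:], truth.sides[1:]):
            j = np.argmin(np.abs(det - t))
            if abs(det[j] - t) < 0.01:
                agree.append(hs["side"].iloc[j] == side)
        assert np.mean(agree) > 0.999

    def test_nonuniform_time_vector_rejected(self):
        t = np.concatenate([np.arange(0, 1, 0.001), np.arange(1, 2, 0.002)])
        x = np.zeros(len(t))
        with pytest.raises(ValueError, match="uniform"):
            detect_heel_strikes_cop(x, x, 1000.0, "steady", time=t)


class TestForceEvents:
    rate = 1000.0

    def test_ramp_crossing_detected_at_threshold_time(self):
        t = np.arange(0, 2, 1 / self.rate)
        fz = np.clip((t - 0.5) * 800.0, 0.0, 800.0)  # crosses 100 N at 0.625 s
        ev = detect_events_force(fz, np.zeros_like(fz), self.rate, prefiltered=True)
        hs = ev[ev["type"] == "heel_strike"]
        assert len(hs) == 1
        assert hs["time_s"].iloc[0] == pytest.approx(0.625, abs=0.002)
        assert hs["side"].iloc[0] == "left"

    def test_subthreshold_noise_gives_no_events(self, rng):
        fz = 40.0 + 20.0 * rng.uniform(-1, 1, 3000)
        ev = detect_events_force(fz, fz, self.rate, prefiltered=True)
        assert len(ev) == 0

    def test_rectangular_stance_gives_one_hs_and_one_to(self):
        fz = np.zeros(3000)
        fz[1000:2000] = 700.0
        ev = detect_events_force(fz, np.zeros_like(fz), self.rate)
        hs = ev[ev["type"] == "heel_strike"]
        to = ev[ev["type"] == "toe_off"]
        assert len(hs) == 1 and len(to) == 1
        assert hs["time_s"].iloc[0] < to["time_s"].iloc[0]


def _make_marker_frame(n, rate, left_xyz, right_xyz):
    return {
        "L_calcaneus": np.tile(left_xyz, (n, 1)).astype(float),
        "R_calcaneus": np.tile(right_xyz, (n, 1)).astype(float),
    }


class TestStutterExclusion:
    def test_high_calcaneus_candidate_invalidated(self):
        n, rate = 600, 100.0
        markers = _make_marker_frame(n, rate, [0.3, 0.1, 0.25], [-0.2, -0.1, 0.02])
        time = np.arange(n) / rate
        events = pd.DataFrame([
            {"time_s": 2.0, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"}])
        out = exclude_stutter_steps(events, markers, time, prefiltered=True)
        assert not out["valid"].iloc[0]
        assert out["reason"].iloc[0] == "marker_height"

    def test_same_front_foot_invalidated(self):
        n, rate = 800, 100.0
        markers = _make_marker_frame(n, rate, [0.3, 0.1, 0.02], [-0.2, -0.1, 0.02])
        time = np.arange(n) / rate
        events = pd.DataFrame([
            {"time_s": 2.0, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"},
            {"time_s": 2.4, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"},
        ])
        out = exclude_stutter_steps(events, markers, time, prefiltered=True)
        assert out["valid"].iloc[0]
        assert not out["valid"].iloc[1]
        assert out["reason"].iloc[1] == "stutter"

    def test_clean_steady_walking_has_zero_exclusions(self, steady_events):
        hs = steady_events[steady_events["type"] == "heel_strike"]
        assert hs["valid"].all()

    def test_injected_stutters_all_excluded_no_proper_steps_lost(
            self, perturbed_trial, perturbed_events):
        truth = perturbed_trial.truth
        assert len(truth.stutter_times) > 0
        invalid = perturbed_events[(perturbed_events["type"] == "heel_strike")
                                   & ~perturbed_events["valid"]]
        inv_t = invalid["time_s"].to_numpy()
        for t in truth.stutter_times:
            assert np.any(np.abs(inv_t - t) < 0.12)
        for t in inv_t:  # nothing excluded near a genuine footfall
            assert np.min(np.abs(truth.heel_strike_times - t)) > 0.05

    def test_sides_alternate_after_exclusion(self, perturbed_events):
        hs = valid_heel_strikes(perturbed_events)
        sides = hs["side"].to_numpy()
        assert np.all(sides[1:] != sides[:-1])


class TestMidstance:
    def test_midpoint_of_stance(self):
        events = pd.DataFrame([
            {"time_s": 1.0, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"},
            {"time_s": 1.7, "type": "toe_off", "side": "left",
             "source": "force", "valid": True, "reason": "none"},
        ])
        mid = find_midstance(events)
        assert len(mid) == 1
        assert mid["time_s"].iloc[0] == pytest.approx(1.35)

    def test_stance_without_toe_off_skipped(self):
        events = pd.DataFrame([
            {"time_s": 1.0, "type": "heel_strike", "side": "left",
             "source": "cop", "valid": True, "reason": "none"}])
        assert len(find_midstance(events)) == 0

    def test_detected_midstances_match_ground_truth(self, perturbed_trial,
                                                    perturbed_events):
        truth = perturbed_trial.truth
        mid = find_midstance(perturbed_events)
        left = mid[mid["side"] == "left"]["time_s"].to_numpy()
        for onset in truth.perturbations["onset_s"]:
            assert np.min(np.abs(left - onset)) < 0.02

    def test_merge_preserves_and_sorts(self):
        a = pd.DataFrame([{"time_s": 2.0, "type": "heel_strike", "side": "left",
                           "source": "cop", "valid": True, "reason": "none"}])
        b = pd.DataFrame([{"time_s": 1.0, "type": "toe_off", "side": "right",
                           "source": "force", "valid": True, "reason": "none"}])
        merged = merge_event_tables(a, b)
        assert merged["time_s"].is_monotonic_increasing
        assert len(merged) == 2
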