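import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gaitbalance.detection_eval import (
    StepPool,
    bootstrap_accuracy,
    cohort_detect_loso,
    metric_from_pool,
    subject_specific_detect,
    weighted_accuracy,
)

CONDITIONS = ("normal", "braces", "eyes_blocked", "jets")


def score_table(values_by_subject):
    rows = []
    for subj, vals in values_by_subject.items():
        for cond, v in zip(CONDITIONS, vals):
            rows.append({"subject": subj, "condition": cond, "value": v})
    return pd.DataFrame(rows)


def separable_table(n_subjects=10, base=1.0, worse=1.2, spread=0.0):
    rng = np.random.default_rng(0)
    return score_table({
        f"S{i:02d}": [base + spread * rng.normal()] + [worse + spread * rng.normal()] * 3
        for i in range(n_subjects)})


class TestWeightedAccuracy:
    def test_constant_classifier_scores_exactly_half(self):
        y_true = np.array([False] * 10 + [True] * 30)
        for const in (True, False):
            y_pred = np.full(40, const)
            assert weighted_accuracy(y_true, y_pred) == pytest.approx(0.5, abs=1e-12)

    @given(n_pos=st.integers(1, 30), n_neg=st.integers(1, 30))
    @settings(max_examples=25, deadline=None)
    def test_chance_level_is_half_for_any_imbalance(self, n_pos, n_neg):
        y_true = np.array([True] * n_pos + [False] * n_neg)
        y_pred = np.full(n_pos + n_neg, True)
        assert weighted_accuracy(y_true, y_pred) == pytest.approx(0.5, abs=1e-12)

    def test_perfect_prediction_scores_one(self):
        y = np.array([True, False, True, True])
        assert weighted_accuracy(y, y) == 1.0


class TestSubjectSpecific:
    def test_worse_score_detected(self):
        res = subject_specific_detect(score_table({"S1": [1.0, 1.2, 1.1, 1.3]}))
        assert res.accuracy == 1.0

    def test_tie_with_baseline_not_detected(self):
        res = subject_specific_detect(score_table({"S1": [1.0, 1.0, 1.2, 1.2]}))
        assert res.accuracy == pytest.approx(2 / 3)

    def test_lower_is_worse_metrics_flip_direction(self):
        res = subject_specific_detect(score_table({"S1": [1.0, 0.8, 0.9, 1.4]}),
                                      higher_is_worse=False)
        assert res.accuracy == pytest.approx(2 / 3)

    def test_30_comparisons_for_10_subjects(self):
        res = subject_specific_detect(separable_table())
        assert res.n_comparisons == 30
        assert res.accuracy == 1.0

    def test_missing_baseline_rejected(self):
        table = separable_table()
        table = table[~((table["subject"] == "S03")
                        & (table["condition"] == "normal"))]
        with pytest.raises(ValueError, match="unimpaired"):
            subject_specific_detect(table)


class TestCohortLoso:
    def test_perfect_separation_gives_accuracy_one(self):
        res = cohort_detect_loso(separable_table())
        assert res.accuracy == 1.0
        assert res.n_comparisons == 40  # 10 folds x 4 conditions

    def test_scores_independent_of_labels_near_chance(self):
        rng = np.random.default_rng(5)
        accs = []
        for rep in range(30):
            table = score_table({f"S{i:02d}": rng.normal(1.0, 0.1, 4)
                                 for i in range(10)})
            accs.append(cohort_detect_loso(table).accuracy)
        # weighted chance level is 50%; fold-mean estimate has sampling noise
        assert np.mean(accs) == pytest.approx(0.5, abs=0.06)

    def test_fewer_than_three_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            cohort_detect_loso(separable_table(n_subjects=2))


def make_pools(rng, n_subjects=6, effect=2.0, n_steps=570):
    pools = {}
    for i in range(n_subjects):
        for cond in CONDITIONS:
            sd = 0.01 * (effect if cond != "normal" else 1.0)
            pos = rng.normal(0.05, 0.01, n_steps)
            vel = rng.normal(0.2, 0.05, n_steps)
            eps = rng.normal(0, sd, n_steps)
            pools[(f"S{i}", cond)] = StepPool(
                subject=f"S{i}", condition=cond,
                widths=rng.normal(0.12, sd, n_steps),
                step_times=rng.normal(0.55, sd, n_steps),
                sides=np.tile(["left", "right"], n_steps // 2 + 1)[:n_steps],
                com_rel_pos=pos, com_vel=vel,
                placements=1.2 * pos + 0.3 * vel + eps)
    return pools


class TestBootstrap:
    def test_step_draw_size_and_determinism(self, rng):
        pools = make_pools(rng)
        a = bootstrap_accuracy(pools, "step_width_variability",
                               "subject_specific", 10, seed=3)
        b = bootstrap_accuracy(pools, "step_width_variability",
                               "subject_specific", 10, seed=3)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert a.n_samples == 10
        assert a.resample_fraction == 0.7

    def test_different_seeds_agree_within_monte_carlo_error(self, rng):
        pools = make_pools(rng, effect=1.15)
        a = bootstrap_accuracy(pools, "step_width_variability",
                               "subject_specific", 60, seed=1)
        b = bootstrap_accuracy(pools, "step_width_variability",
                               "subject_specific", 60, seed=2)
        se = np.sqrt(a.sd ** 2 + b.sd ** 2) / np.sqrt(60)
        assert abs(a.mean - b.mean) < 3 * max(se, 1e-3)

    def test_degenerate_pools_give_zero_variance_distribution(self):
        # constant widths make every resampled metric identical across draws
        pools = {}
        for i in range(4):
            for j, cond in enumerate(CONDITIONS):
                w = np.full(570, 0.1 + 0.01 * j)
                pools[(f"S{i}", cond)] = StepPool(
                    subject=f"S{i}", condition=cond, widths=w,
                    step_times=w, sides=np.tile(["left", "right"], 285),
                    com_rel_pos=w, com_vel=w * 2, placements=w)
        dist = bootstrap_accuracy(pools, "step_width_variability",
                                  "subject_specific", 20, seed=0)
        assert dist.sd == 0.0

    def test_placement_model_refitted_inside_draw(self, rng):
        pools = make_pools(rng, effect=3.0)
        dist = bootstrap_accuracy(pools, "foot_placement_predictability",
                                  "subject_specific", 20, seed=0)
        assert dist.mean > 0.9

    def test_too_few_samples_rejected(self, rng):
        pools = make_pools(rng)
        with pytest.raises(ValueError, match="n_samples"):
            bootstrap_accuracy(pools, "step_width_variability",
                               "subject_specific", 1, seed=0)


class TestMetricFromPool:
    def test_resampled_width_sd_matches_direct_computation(self, rng):
        pools = make_pools(rng, n_subjects=1)
        pool = pools[("S0", "normal")]
        idx = rng.integers(0, 570, 400)
        got = metric_from_pool(pool, "step_width_variability", idx)
        assert got == pytest.approx(np.std(pool.widths[idx], ddof=1))

    def test_unknown_metric_rejected(self, rng):
        pools = make_pools(rng, n_subjects=1)
        with pytest.raises(ValueError, match="unknown"):
            metric_from_pool(pools[("S0", "normal")], "nope")
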