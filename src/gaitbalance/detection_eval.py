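"""Impairment detection under subject-specific vs cohort-based thresholds.

A metric score table (one value per subject x condition) is turned into
binary impairment detections two ways:

* subject-specific — each subject's unimpaired score is their threshold; an
  impaired condition is detected iff its score is strictly worse;
* cohort-based — a weighted logistic regression on the scalar score,
  leave-one-subject-out: class weights are inversely proportional to class
  frequency so a constant classifier scores exactly 50 % weighted accuracy,
  and fold accuracies use the same inverse-frequency weighting (balanced
  accuracy) before averaging across folds.

Bootstrap uncertainty resamples the underlying steps (400 of 570) or strides
(99 of 144) with replacement per subject x condition, recomputes every
metric (refitting placement models inside the draw) and repeats the
detection, yielding a distribution of accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .balance_metrics import (
    EmbeddedTrajectory,
    fit_foot_placement_model,
    max_lyapunov,
    pooled_demeaned_sd,
)

__all__ = [
    "DetectionResult",
    "BootstrapDistribution",
    "StepPool",
    "weighted_accuracy",
    "subject_specific_detect",
    "cohort_detect_loso",
    "bootstrap_accuracy",
    "metric_from_pool",
    "BOOTSTRAP_STEP_DRAW",
    "BOOTSTRAP_STRIDE_DRAW",
    "BOOTSTRAP_SAMPLES",
    "BOOTSTRAP_SAMPLES_LYAPUNOV",
]

BOOTSTRAP_STEP_DRAW = 400      # of the 570 selected steps (the printed 70 %)
BOOTSTRAP_STRIDE_DRAW = 99     # of the 144 selected strides
BOOTSTRAP_SAMPLES = 1000
BOOTSTRAP_SAMPLES_LYAPUNOV = 100
RESAMPLE_FRACTION = 0.7


@dataclass
class DetectionResult:
    threshold_type: str            # 'subject_specific' | 'cohort'
    metric: str
    regime: str
    accuracy: float
    comparisons: pd.DataFrame      # subject, condition, predicted, truth
    n_comparisons: int


@dataclass
class BootstrapDistribution:
    metric: str
    threshold_type: str
    regime: str
    accuracies: np.ndarray
    n_samples: int
    resample_fraction: float
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass
class StepPool:
    """The raw per-subject-condition data a metric consumes, at full budget."""

    subject: str
    condition: str
    widths: np.ndarray = field(default_factory=lambda: np.empty(0))
    step_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    sides: np.ndarray = field(default_factory=lambda: np.empty(0))
    com_rel_pos: np.ndarray = field(default_factory=lambda: np.empty(0))
    com_vel: np.ndarray = field(default_factory=lambda: np.empty(0))
    placements: np.ndarray = field(default_factory=lambda: np.empty(0))
    embedded: EmbeddedTrajectory | None = None


def weighted_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Accuracy with per-sample weights inversely proportional to the true
    class frequency.  A constant prediction scores exactly 0.5 for binary
    labels regardless of class imbalance."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    classes, counts = np.unique(y_true, return_counts=True)
    w = np.empty(len(y_true), dtype=float)
    for cls, cnt in zip(classes, counts):
        w[y_true == cls] = 1.0 / cnt
    return float(np.sum(w * (y_true == y_pred)) / np.sum(w))


def _check_scores(scores: pd.DataFrame, unimpaired: str) -> None:
    need = {"subject", "condition", "value"}
    if not need.issubset(scores.columns):
        raise ValueError(f"scores table must have columns {sorted(need)}")
    for subj, grp in scores.groupby("subject"):
        if (grp["condition"] == unimpaired).sum() != 1:
            raise ValueError(f"subject {subj} must have exactly one unimpaired "
                             f"({unimpaired!r}) score")


def subject_specific_detect(scores: pd.DataFrame, unimpaired: str = "normal",
                            higher_is_worse: bool = True, *,
                            metric: str = "", regime: str = "steady") -> DetectionResult:
    """Detect each impaired condition against the same subject's baseline.

    An impaired score ties with the baseline are classified unimpaired
    (strict inequality)."""
    _check_scores(scores, unimpaired)
    rows = []
    for subj, grp in scores.groupby("subject"):
        base = float(grp.loc[grp["condition"] == unimpaired, "value"].iloc[0])
        for _, r in grp[grp["condition"] != unimpaired].iterrows():
            worse = r["value"] > base if higher_is_worse else r["value"] < base
            rows.append({"subject": subj, "condition": r["condition"],
                         "predicted": bool(worse), "truth": True})
    comp = pd.DataFrame(rows)
    if comp.empty:
        raise ValueError("no impaired conditions to compare")
    acc = float(comp["predicted"].mean())
    return DetectionResult("subject_specific", metric, regime, acc, comp, len(comp))


def cohort_detect_loso(scores: pd.DataFrame, unimpaired: str = "normal", *,
                       metric: str = "", regime: str = "steady",
                       C: float = 1e6) -> DetectionResult:
    """Leave-one-subject-out weighted logistic regression on the scalar score.

    Class weights are inversely proportional to training-fold class frequency
    (sklearn's ``balanced``); held-out predictions are thresholded at
    probability 0.5 and each fold is scored with the same inverse-frequency
    weighting before averaging.
    """
    _check_scores(scores, unimpaired)
    subjects = sorted(scores["subject"].unique())
    if len(subjects) < 3:
        raise ValueError("cohort detection needs at least 3 subjects")
    fold_accs = []
    rows = []
    for held in subjects:
        train = scores[scores["subject"] != held]
        test = scores[scores["subject"] == held]
        y_train = (train["condition"] != unimpaired).to_numpy()
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {held}: single-class training data, fold skipped")
            continue
        x = train["value"].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std() or 1.0
        model = LogisticRegression(class_weight="balanced", C=C, max_iter=1000)
        model.fit(((x - mu) / sd)[:, None], y_train)
        x_test = (test["value"].to_numpy(dtype=float) - mu) / sd
        pred = model.predict(x_test[:, None])
        truth = (test["condition"] != unimpaired).to_numpy()
        fold_accs.append(weighted_accuracy(truth, pred))
        for cond, p, tr in zip(test["condition"], pred, truth):
            rows.append({"subject": held, "condition": cond,
                         "predicted": bool(p), "truth": bool(tr)})
    if not fold_accs:
        raise ValueError("all folds degenerate; cannot evaluate cohort threshold")
    comp = pd.DataFrame(rows)
    return DetectionResult("cohort", metric, regime, float(np.mean(fold_accs)),
                           comp, len(comp))


# ---------------------------------------------------------------------------
# metric recomputation from raw pools (used by the bootstrap)
# ---------------------------------------------------------------------------

def metric_from_pool(pool: StepPool, metric: str,
                     indices: np.ndarray | None = None) -> float:
    """Recompute a metric from a pool, optionally on a resampled index set."""
    if metric == "step_width_variability":
        w = pool.widths if indices is None else pool.widths[indices]
        return float(np.std(w, ddof=1))
    if metric == "step_time_variability":
        idx = slice(None) if indices is None else indices
        return pooled_demeaned_sd(pool.step_times[idx], pool.sides[idx])
    if metric == "foot_placement_predictability":
        idx = slice(None) if indices is None else indices
        _, sd = fit_foot_placement_model(pool.com_rel_pos[idx], pool.com_vel[idx],
                                         pool.placements[idx])
        return sd
    if metric == "max_lyapunov":
        if pool.embedded is None:
            raise ValueError("pool has no embedded trajectory for the Lyapunov metric")
        return max_lyapunov(pool.embedded, stride_subset=indices).value
    raise ValueError(f"unknown pool metric {metric!r}")


def _detect(scores: pd.DataFrame, threshold_type: str, unimpaired: str,
            metric: str, regime: str) -> DetectionResult:
    if threshold_type == "subject_specific":
        return subject_specific_detect(scores, unimpaired, metric=metric, regime=regime)
    if threshold_type == "cohort":
        return cohort_detect_loso(scores, unimpaired, metric=metric, regime=regime)
    raise ValueError(f"unknown threshold_type {threshold_type!r}")


def bootstrap_accuracy(pools: dict[tuple[str, str], StepPool], metric: str,
                       threshold_type: str, n_samples: int, seed: int, *,
                       unimpaired: str = "normal", regime: str = "steady",
                       step_draw: int = BOOTSTRAP_STEP_DRAW,
                       stride_draw: int = BOOTSTRAP_STRIDE_DRAW) -> BootstrapDistribution:
    """Bootstrap distribution of detection accuracy.

    Per sample, each subject x condition's steps (``step_draw`` of the pool,
    with replacement) or strides (``stride_draw``) are redrawn, the metric
    recomputed — placement models refitted inside the draw — and the chosen
    detection run.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    is_stride = metric == "max_lyapunov"
    accs = np.empty(n_samples)
    keys = sorted(pools)
    for s in range(n_samples):
        rows = []
        for key in keys:
            pool = pools[key]
            if is_stride:
                n = pool.embedded.n_strides
                idx = rng.integers(0, n, size=stride_draw)
            else:
                n = len(pool.widths)
                idx = rng.integers(0, n, size=step_draw)
            rows.append({"subject": pool.subject, "condition": pool.condition,
                         "value": metric_from_pool(pool, metric, idx)})
        result = _detect(pd.DataFrame(rows), threshold_type, unimpaired, metric, regime)
        accs[s] = result.accuracy
    return BootstrapDistribution(metric=metric, threshold_type=threshold_type,
                                 regime=regime, accuracies=accs, n_samples=n_samples,
                                 resample_fraction=RESAMPLE_FRACTION, seed=seed)
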