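"""Nonparametric comparisons of accuracy distributions and learning effects.

All tests are nonparametric: Wilcoxon signed-rank for paired comparisons
(subject-specific vs cohort thresholds, steady vs steady-plus-perturbation
data, learning-effect slopes vs zero), a Kruskal-Wallis omnibus across
metrics followed by a rank-sum contrast of the variability-based metrics
against the rest.  Significance uses a Bonferroni-corrected alpha of 0.0071
(0.05 over the seven planned comparisons, as printed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonReport",
    "LearningEffectResult",
    "compare_paired",
    "compare_metric_groups",
    "learning_effect",
    "ALPHA_CORRECTED",
    "VARIABILITY_METRICS",
]

ALPHA_CORRECTED = 0.0071
EXACT_P_MAX_N = 25  # exact signed-rank p-values up to here, normal approx beyond
VARIABILITY_METRICS = ("step_width_variability", "step_time_variability",
                       "foot_placement_predictability")


@dataclass
class ComparisonReport:
    test_name: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    alpha: float = ALPHA_CORRECTED

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def narrative(self) -> str:
        verdict = "significant" if self.significant else "not significant"
        return (f"{self.test_name} on {', '.join(self.groups)}: statistic="
                f"{self.statistic:.4g}, p={self.p_value:.3g} ({verdict} at "
                f"alpha={self.alpha})")


def _signed_rank(diff: np.ndarray) -> tuple[float, float]:
    diff = np.asarray(diff, dtype=float)
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    method = "exact" if len(nz) <= EXACT_P_MAX_N else "approx"
    try:
        res = stats.wilcoxon(nz, method=method, correction=(method == "approx"))
    except TypeError:  # older scipy spelling
        res = stats.wilcoxon(nz, mode=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def compare_paired(dist_a: np.ndarray, dist_b: np.ndarray, *,
                   names: tuple[str, str] = ("a", "b"),
                   test_name: str = "Wilcoxon signed-rank",
                   alpha: float = ALPHA_CORRECTED) -> ComparisonReport:
    """Wilcoxon signed-rank test on paired accuracy distributions."""
    dist_a = np.asarray(dist_a, dtype=float)
    dist_b = np.asarray(dist_b, dtype=float)
    if dist_a.shape != dist_b.shape:
        raise ValueError("paired distributions must have equal length")
    stat, p = _signed_rank(dist_b - dist_a)
    return ComparisonReport(test_name, names, stat, p, alpha)


def compare_metric_groups(distributions: dict[str, np.ndarray], *,
                          variability_group: tuple[str, ...] = VARIABILITY_METRICS,
                          alpha: float = ALPHA_CORRECTED
                          ) -> tuple[ComparisonReport, ComparisonReport]:
    """Kruskal-Wallis omnibus across metrics, then a rank-sum contrast of the
    variability-based group against the remaining metrics."""
    if len(distributions) < 2:
        raise ValueError("need at least two metric distributions")
    names = tuple(distributions)
    stat, p = stats.kruskal(*[np.asarray(distributions[k], float) for k in names])
    omnibus = ComparisonReport("Kruskal-Wallis omnibus", names, float(stat), float(p),
                               alpha)
    grp_a = [np.asarray(distributions[k], float) for k in names if k in variability_group]
    grp_b = [np.asarray(distributions[k], float) for k in names
             if k not in variability_group]
    if not grp_a or not grp_b:
        raise ValueError("contrast needs metrics inside and outside the variability group")
    a = np.concatenate(grp_a)
    b = np.concatenate(grp_b)
    res = stats.ranksums(a, b)
    contrast = ComparisonReport(
        "Wilcoxon rank-sum contrast (variability vs other metrics)",
        ("variability", "other"), float(res.statistic), float(res.pvalue), alpha)
    return omnibus, contrast


@dataclass
class LearningEffectResult:
    slopes: pd.DataFrame            # subject, condition, slope (units/min)
    first_window_values: pd.DataFrame
    last_window_values: pd.DataFrame
    report: ComparisonReport = field(default=None)


def learning_effect(step_series: dict[tuple[str, str], pd.DataFrame],
                    metric, *, value_column: str = "width_m",
                    window: int = 200, stride: int = 100,
                    alpha: float = ALPHA_CORRECTED,
                    test_name: str = "Wilcoxon signed-rank (slopes vs 0)"
                    ) -> LearningEffectResult:
    """Within-condition drift of a metric over time.

    For each subject x condition the metric is evaluated on windows of
    ``window`` steps sliding by ``stride`` steps; an OLS line of metric value
    against window mid-time gives a slope in metric units per minute.  The
    metric is also computed on the first and last ``window`` steps.  A
    Wilcoxon signed-rank test asks whether the slopes differ from zero.

    ``metric`` is a callable mapping ``(values, sides)`` arrays to a scalar
    (e.g. a standard deviation).
    """
    slope_rows, first_rows, last_rows = [], [], []
    for (subj, cond), steps in step_series.items():
        vals = steps[value_column].to_numpy(dtype=float)
        sides = steps["side"].to_numpy() if "side" in steps.columns \
            else np.zeros(len(steps))
        t = steps["time_s"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        vals, sides, t = vals[ok], sides[ok], t[ok]
        if len(vals) < 2 * window:
            raise ValueError(f"{subj}/{cond}: need >= {2 * window} steps, "
                             f"have {len(vals)}")
        mids, ys = [], []
        for lo in range(0, len(vals) - window + 1, stride):
            sl = slice(lo, lo + window)
            ys.append(metric(vals[sl], sides[sl]))
            mids.append(t[sl].mean() / 60.0)
        slope = float(np.polyfit(np.asarray(mids), np.asarray(ys), 1)[0])
        slope_rows.append({"subject": subj, "condition": cond, "slope_per_min": slope})
        first_rows.append({"subject": subj, "condition": cond,
                           "value": metric(vals[:window], sides[:window])})
        last_rows.append({"subject": subj, "condition": cond,
                          "value": metric(vals[-window:], sides[-window:])})
    slopes = pd.DataFrame(slope_rows)
    stat, p = _signed_rank(slopes["slope_per_min"].to_numpy())
    report = ComparisonReport(test_name, ("slopes", "zero"), stat, p, alpha)
    return LearningEffectResult(slopes=slopes,
                                first_window_values=pd.DataFrame(first_rows),
                                last_window_values=pd.DataFrame(last_rows),
                                report=report)
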