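"""End-to-end plumbing: trials -> events -> step/stride pools -> metric scores.

These helpers run the full measurement chain on generated (or loaded) trial
groups and hand the fixed-budget raw pools to the detection / bootstrap
layer.  Cohort-scale processing streams one subject x condition at a time so
signal arrays are released as soon as their pools are extracted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import balance_metrics as bm
from .detection_eval import StepPool
from .gait_events import detect_trial_events, valid_heel_strikes
from .signal_io import TrialTimeSeries, estimate_com, zero_lag_butterworth
from .synthetic_gait import SyntheticCohortConfig, SyntheticTrial, draw_subject_params, \
    generate_trial

__all__ = [
    "group_step_pool",
    "cohort_pools",
    "c7_velocity",
    "left_stride_bounds",
    "group_lyapunov_embedding",
]


def c7_velocity(trial: TrialTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """3-D C7 marker velocity (lab frame), 25 Hz zero-lag filtered."""
    rate = trial.marker_rate
    vel = np.gradient(trial.markers["C7"], 1.0 / rate, axis=0)
    return trial.marker_time, zero_lag_butterworth(vel, 4, bm.COM_CUTOFF_HZ, rate)


def left_stride_bounds(events: pd.DataFrame) -> list[tuple[float, float]]:
    """Strides delimited by consecutive left-foot heel strikes."""
    hs = valid_heel_strikes(events)
    left = hs[hs["side"] == "left"]["time_s"].to_numpy()
    return [(float(left[i]), float(left[i + 1])) for i in range(len(left) - 1)]


def group_step_pool(trials: list[SyntheticTrial], regime: str = "steady", *,
                    subject: str = "", condition: str = "",
                    budget: int = bm.STEP_BUDGET,
                    include_lyapunov: bool = False) -> StepPool:
    """Detect events, build the step series, apply the regime rules and trim
    to the fixed budget for one subject x condition trial group."""
    all_steps = []
    session_offset = 0.0
    processed = []
    for st in trials:
        trial = st.trial
        events = detect_trial_events(trial)
        com = estimate_com(trial.pelvis_markers(), trial.marker_rate,
                           time=trial.marker_time)
        steps = bm.trial_step_series(trial, events, com)
        processed.append((trial, events, com, steps))
        sel = bm.select_regime(steps, st.truth.perturbations, regime).copy()
        sel["session_time_s"] = sel["time_s"] + session_offset
        all_steps.append(sel)
        session_offset += float(trial.meta.get("duration_s",
                                               trial.marker_time[-1])) + 60.0
    pooled = pd.concat(all_steps, ignore_index=True)
    ok = pooled[["width_m", "step_time_s", "placement_m",
                 "com_rel_pos_m", "com_vel_mps"]].notna().all(axis=1)
    pooled = pooled[ok].reset_index(drop=True)
    if len(pooled) < budget:
        raise bm.ShortfallError(
            f"{subject}/{condition}: {len(pooled)} qualifying steps, budget {budget}")
    pooled = pooled.iloc[:budget]

    pool = StepPool(
        subject=subject, condition=condition,
        widths=pooled["width_m"].to_numpy(),
        step_times=pooled["step_time_s"].to_numpy(),
        sides=pooled["side"].to_numpy(),
        com_rel_pos=pooled["com_rel_pos_m"].to_numpy(),
        com_vel=pooled["com_vel_mps"].to_numpy(),
        placements=pooled["placement_m"].to_numpy(),
    )
    if include_lyapunov:
        pool.embedded = group_lyapunov_embedding(processed, regime)
    return pool


def group_lyapunov_embedding(processed, regime: str) -> bm.EmbeddedTrajectory:
    """144-stride delay embedding of C7 velocity for one trial group.

    ``processed`` is a list of (trial, events, com, steps) tuples in session
    order.  The steady regime takes 8 sections x 9 strides from each of the
    two unperturbed trials; the perturbed regime takes 9 strides around each
    of the 16 onsets (onset in the fifth stride).
    """
    steady = [(t, e) for t, e, _, _ in processed if t.meta.get("kind") == "steady"]
    perturbed = [(t, e) for t, e, _, _ in processed if t.meta.get("kind") == "perturbed"]
    groups: list[tuple[TrialTimeSeries, list[tuple[float, float]]]] = []
    if regime == "steady":
        bounds = [left_stride_bounds(e) for _, e in steady]
        grouped = bm.lyapunov_strides_steady(bounds)
        per_trial = len(grouped) // 2
        for i, g in enumerate(grouped):
            groups.append((steady[0][0] if i < per_trial else steady[1][0], g))
    else:
        if not perturbed:
            raise ValueError("perturbed regime requires a perturbation trial")
        trial, events = perturbed[-1]
        bounds = left_stride_bounds(events)
        onsets = trial.meta.get("perturbation_onsets")
        if onsets is None:
            raise ValueError("perturbed trial lacks 'perturbation_onsets' metadata")
        for g in bm.lyapunov_strides_perturbed(bounds, np.asarray(onsets)):
            groups.append((trial, g))

    stacks, segments = [], []
    vel_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for seg_id, (trial, g) in enumerate(groups):
        key = id(trial)
        if key not in vel_cache:
            vel_cache[key] = c7_velocity(trial)
        t, v = vel_cache[key]
        stacks.append(bm.time_normalize_strides(v, t, g))
        segments.append(np.full(len(g), seg_id))
    stack = np.concatenate(stacks, axis=0)
    seg = np.concatenate(segments)
    if len(stack) != bm.STRIDE_BUDGET:
        raise bm.ShortfallError(
            f"Lyapunov selection produced {len(stack)} strides, budget {bm.STRIDE_BUDGET}")
    return bm.delay_embed(stack, seg)


def cohort_pools(config: SyntheticCohortConfig, regime: str = "steady", *,
                 include_perturbation_bout: bool = False,
                 budget: int = bm.STEP_BUDGET,
                 include_lyapunov: bool = False) -> dict[tuple[str, str], StepPool]:
    """Generate and process a synthetic cohort, streaming one group at a time.

    With ``include_perturbation_bout=False`` only the two steady trials are
    generated, which is sufficient for the steady regime of the step-based
    metrics and keeps cohort-scale memory use flat.
    """
    config.validate()
    pools: dict[tuple[str, str], StepPool] = {}
    kinds = ["steady", "perturbed", "steady"] if include_perturbation_bout \
        else ["steady", "steady"]
    for si in range(config.n_subjects):
        sparams = draw_subject_params(config, si)
        for ci, cond in enumerate(config.conditions):
            cparams = sparams.under(config.impairment_multipliers[cond])
            try:
                pools[(sparams.subject, cond)] = _group_pool(
                    cparams, config, cond, si, ci, kinds, regime, budget,
                    include_lyapunov)
            except bm.ShortfallError:
                if include_perturbation_bout:
                    raise
                # slow-stepping subjects may not fill the budget from the two
                # steady trials alone; the protocol's steady pool also draws
                # pre-perturbation steps from the bout
                pools[(sparams.subject, cond)] = _group_pool(
                    cparams, config, cond, si, ci,
                    ["steady", "perturbed", "steady"], regime, budget,
                    include_lyapunov)
    return pools


def _group_pool(cparams, config, cond, si, ci, kinds, regime, budget,
                include_lyapunov) -> StepPool:
    group = []
    for ti, kind in enumerate(kinds):
        st = generate_trial(cparams, config, kind,
                            duration=config.steady_trial_duration,
                            seed=(config.seed, si, ci, ti))
        st.trial.meta["condition"] = cond
        if st.truth.perturbations is not None:
            st.trial.meta["perturbation_onsets"] = \
                st.truth.perturbations["onset_s"].tolist()
        group.append(st)
    return group_step_pool(group, regime,
                           subject=cparams.subject, condition=cond,
                           budget=budget, include_lyapunov=include_lyapunov)
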