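"""The six balance metrics, data-regime selection and fixed step/stride budgets.

Metrics (all oriented so that a higher value indicates worse balance):

* step-width variability — SD of signed medial-lateral calcaneus separation
  at heel strike (negative when the feet are crossed), over 570 steps;
* step-time variability — per-side demeaned step times pooled, then SD,
  over 570 steps;
* foot-placement predictability — residual SD of a per-subject,
  per-condition OLS model predicting ML swing-foot placement (relative to
  the stance calcaneus) from the ML CoM position (stance-calcaneus frame)
  and ML CoM velocity (lab frame) at midstance;
* maximum Lyapunov exponent — short-term slope of the mean log divergence
  of nearest-neighbour trajectories in a delay-embedded C7-velocity state
  space (d=5 copies, delay T=10 normalized timesteps, 100 samples per
  stride, 144 strides);
* lateral margin of stability — mean lateral distance from the extrapolated
  CoM (CoM + velocity / pendulum natural frequency) to the leading foot's
  fifth-metatarsal marker at heel strike, over 570 steps;
* CoM displacement — mean ML CoM travel between the perturbation-onset
  left-leg midstance and the next left-leg midstance, for the two 7.5 %BW
  rightward perturbations.

Standard deviations use the n-1 denominator.  Budget trimming takes the
chronologically first qualifying steps of the regime pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import (
    COM_CUTOFF_HZ,
    FOOT_MARKER_CUTOFF_HZ,
    ComState,
    TrialTimeSeries,
    estimate_com,
    interp_at,
    zero_lag_butterworth,
)
from .gait_events import detect_trial_events, find_midstance, valid_heel_strikes

__all__ = [
    "MetricScore",
    "EmbeddedTrajectory",
    "STEP_BUDGET",
    "STRIDE_BUDGET",
    "GRAVITY",
    "compute_step_series",
    "select_regime",
    "step_width_variability",
    "step_time_variability",
    "pooled_demeaned_sd",
    "fit_foot_placement_model",
    "foot_placement_predictability",
    "time_normalize_strides",
    "delay_embed",
    "max_lyapunov",
    "margin_of_stability",
    "pendulum_natural_frequency",
    "extrapolated_com",
    "com_displacement",
    "lyapunov_strides_steady",
    "lyapunov_strides_perturbed",
    "trial_step_series",
]

STEP_BUDGET = 570     # steps, the cross-subject minimum the analysis trims to
STRIDE_BUDGET = 144   # strides entering each Lyapunov estimate
SAMPLES_PER_STRIDE = 100
EMBED_COPIES = 5      # d
EMBED_DELAY = 10      # T, normalized timesteps
GRAVITY = 9.81        # m/s^2

REGIMES = ("steady", "steady_plus_perturbation", "perturbation_only")
PRE_PERTURBATION_WINDOW = (18.0, 23.0)  # s after the previous onset
POST_PERTURBATION_WINDOW = 7.0          # s after each onset


@dataclass
class MetricScore:
    subject: str
    condition: str
    metric: str
    value: float
    regime: str
    higher_is_worse: bool = True
    n_used: int = 0


class ShortfallError(ValueError):
    """Raised when a subject/condition cannot fill the fixed step/stride budget."""


def _require_budget(n: int, budget: int, what: str, subject: str = "", condition: str = ""):
    if n < budget:
        where = f" for {subject}/{condition}" if subject or condition else ""
        raise ShortfallError(f"{what}: only {n} available{where}, budget is {budget}")


# ---------------------------------------------------------------------------
# step series
# ---------------------------------------------------------------------------

def trial_step_series(trial: TrialTimeSeries, events: pd.DataFrame | None = None,
                      com: ComState | None = None) -> pd.DataFrame:
    """Event detection (if needed) + step geometry for one trial."""
    if events is None:
        events = detect_trial_events(trial)
    if com is None:
        com = estimate_com(trial.pelvis_markers(), trial.marker_rate,
                           time=trial.marker_time)
    steps = compute_step_series(events, trial.markers, trial.marker_time, com)
    steps["trial_kind"] = trial.meta.get("kind", "steady")
    return steps


def compute_step_series(events: pd.DataFrame, markers: dict[str, np.ndarray],
                        marker_time: np.ndarray, com: ComState | None = None, *,
                        prefiltered: bool = False) -> pd.DataFrame:
    """Per-step width, time and foot-placement coordinates from valid events.

    Width is the signed ML calcaneus separation at heel strike (left minus
    right; positive when uncrossed).  The placement coordinate is the landing
    calcaneus ML position relative to the stance calcaneus, paired with the
    CoM state at the preceding midstance when ``com`` is given.
    """
    for name in ("L_calcaneus", "R_calcaneus"):
        if name not in markers:
            raise ValueError(f"calcaneus marker {name!r} missing")
    rate = 1.0 / float(np.median(np.diff(marker_time)))
    filt = {}
    for name in ("L_calcaneus", "R_calcaneus"):
        arr = np.asarray(markers[name], dtype=float)
        filt[name] = arr if prefiltered else zero_lag_butterworth(
            arr, 4, FOOT_MARKER_CUTOFF_HZ, rate)

    hs = valid_heel_strikes(events)
    mid = find_midstance(events)
    rows = []
    for k in range(1, len(hs)):
        t = float(hs.loc[k, "time_s"])
        t_prev = float(hs.loc[k - 1, "time_s"])
        side = hs.loc[k, "side"]
        prev_side = hs.loc[k - 1, "side"]
        if side == prev_side:  # alternation broken; skip and log via NaN row
            continue
        y_l = float(interp_at(marker_time, filt["L_calcaneus"][:, 1], t)[0])
        y_r = float(interp_at(marker_time, filt["R_calcaneus"][:, 1], t)[0])
        width = y_l - y_r
        placement = width if side == "left" else -width
        rel = vel = np.nan
        mid_t = np.nan
        if com is not None and len(mid):
            cand = mid[(mid["side"] == prev_side)
                       & (mid["time_s"] > t_prev) & (mid["time_s"] <= t)]
            if len(cand):
                mid_t = float(cand["time_s"].iloc[-1])
                stance = "L_calcaneus" if prev_side == "left" else "R_calcaneus"
                stance_y = float(interp_at(marker_time, filt[stance][:, 1], mid_t)[0])
                com_y = float(interp_at(com.time, com.position[:, 1], mid_t)[0])
                rel = com_y - stance_y
                vel = float(interp_at(com.time, com.velocity[:, 1], mid_t)[0])
        rows.append({"time_s": t, "side": side, "width_m": width,
                     "step_time_s": t - t_prev, "placement_m": placement,
                     "com_rel_pos_m": rel, "com_vel_mps": vel,
                     "midstance_s": mid_t})
    cols = ["time_s", "side", "width_m", "step_time_s", "placement_m",
            "com_rel_pos_m", "com_vel_mps", "midstance_s"]
    return pd.DataFrame(rows, columns=cols)


def select_regime(steps: pd.DataFrame, perturbation_log: pd.DataFrame | None,
                  regime: str) -> pd.DataFrame:
    """Tag and filter a pooled step series according to the data regime.

    ``steps`` must carry a ``trial_kind`` column (``steady``/``perturbed``).
    The steady regime keeps steady-trial steps plus perturbation-trial steps
    falling 18-23 s after the previous onset; steady_plus_perturbation keeps
    steady-trial steps plus the 7 s after each onset; perturbation_only keeps
    only the post-onset windows.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    if "trial_kind" not in steps.columns:
        raise ValueError("steps must carry a 'trial_kind' column")
    steady_rows = steps["trial_kind"] == "steady"
    pert_steps = steps[~steady_rows]
    onsets = np.sort(perturbation_log["onset_s"].to_numpy()) \
        if perturbation_log is not None and len(perturbation_log) else np.empty(0)

    def in_windows(t: np.ndarray, lo_off: float, hi_off: float,
                   anchor: np.ndarray) -> np.ndarray:
        keep = np.zeros(len(t), dtype=bool)
        for a in anchor:
            keep |= (t > a + lo_off) & (t <= a + hi_off)
        return keep

    t_pert = pert_steps["time_s"].to_numpy()
    if regime == "steady":
        lo, hi = PRE_PERTURBATION_WINDOW
        keep_pert = in_windows(t_pert, lo, hi, onsets)
        out = pd.concat([steps[steady_rows], pert_steps[keep_pert]])
    elif regime == "steady_plus_perturbation":
        keep_pert = in_windows(t_pert, 0.0, POST_PERTURBATION_WINDOW, onsets)
        out = pd.concat([steps[steady_rows], pert_steps[keep_pert]])
    else:
        keep_pert = in_windows(t_pert, 0.0, POST_PERTURBATION_WINDOW, onsets)
        out = pert_steps[keep_pert]
    out = out.copy()
    out["regime"] = regime
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# variability metrics
# ---------------------------------------------------------------------------

def step_width_variability(steps: pd.DataFrame, budget: int = STEP_BUDGET, *,
                           subject: str = "", condition: str = "",
                           regime: str = "steady") -> MetricScore:
    widths = steps["width_m"].to_numpy(dtype=float)
    widths = widths[np.isfinite(widths)]
    _require_budget(len(widths), budget, "step-width variability", subject, condition)
    value = float(np.std(widths[:budget], ddof=1))
    return MetricScore(subject, condition, "step_width_variability", value,
                       regime, True, budget)


def pooled_demeaned_sd(times: np.ndarray, sides: np.ndarray) -> float:
    """SD of step times after demeaning left-landing and right-landing steps
    separately and pooling (removes asymmetry bias)."""
    times = np.asarray(times, dtype=float)
    pooled = times.copy()
    for side in np.unique(sides):
        m = sides == side
        pooled[m] = times[m] - times[m].mean()
    return float(np.std(pooled, ddof=1))


def step_time_variability(steps: pd.DataFrame, budget: int = STEP_BUDGET, *,
                          subject: str = "", condition: str = "",
                          regime: str = "steady") -> MetricScore:
    ok = steps["step_time_s"].notna()
    sel = steps[ok]
    _require_budget(len(sel), budget, "step-time variability", subject, condition)
    sel = sel.iloc[:budget]
    value = pooled_demeaned_sd(sel["step_time_s"].to_numpy(),
                               sel["side"].to_numpy())
    return MetricScore(subject, condition, "step_time_variability", value,
                       regime, True, budget)


def fit_foot_placement_model(com_rel_pos: np.ndarray, com_vel: np.ndarray,
                             placements: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS fit of ML foot placement on midstance CoM state (with intercept).

    Returns ``(coefficients, residual_sd)`` with coefficients ordered
    (intercept, position gain, velocity gain); the residual SD (n-1
    denominator) is the foot-placement-predictability value.
    """
    X = np.column_stack([np.ones(len(placements)), com_rel_pos, com_vel])
    y = np.asarray(placements, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("placement model inputs contain NaN")
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        raise ValueError("placement model inputs are rank deficient "
                         "(constant regressors?)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = float(np.std(resid, ddof=1)) if len(resid) > 1 else 0.0
    return coef, sd


def foot_placement_predictability(steps: pd.DataFrame, budget: int = STEP_BUDGET, *,
                                  subject: str = "", condition: str = "",
                                  regime: str = "steady") -> MetricScore:
    ok = steps[["placement_m", "com_rel_pos_m", "com_vel_mps"]].notna().all(axis=1)
    sel = steps[ok]
    _require_budget(len(sel), budget, "foot-placement predictability", subject, condition)
    sel = sel.iloc[:budget]
    _, sd = fit_foot_placement_model(sel["com_rel_pos_m"].to_numpy(),
                                     sel["com_vel_mps"].to_numpy(),
                                     sel["placement_m"].to_numpy())
    return MetricScore(subject, condition, "foot_placement_predictability", sd,
                       regime, True, budget)


# ---------------------------------------------------------------------------
# Lyapunov exponent
# ---------------------------------------------------------------------------

def time_normalize_strides(signal: np.ndarray, time: np.ndarray,
                           stride_bounds: list[tuple[float, float]],
                           samples_per_stride: int = SAMPLES_PER_STRIDE) -> np.ndarray:
    """Resample each stride to exactly ``samples_per_stride`` samples.

    Linear interpolation with endpoints preserved.  Returns an array of shape
    ``(n_strides, samples_per_stride, n_channels)``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    time = np.asarray(time, dtype=float)
    rate = 1.0 / float(np.median(np.diff(time)))
    out = np.empty((len(stride_bounds), samples_per_stride, signal.shape[1]))
    for i, (t0, t1) in enumerate(stride_bounds):
        if t1 <= t0 or (t1 - t0) * rate < 3:
            raise ValueError(f"stride [{t0}, {t1}] shorter than 3 raw samples")
        ts = np.linspace(t0, t1, samples_per_stride)
        out[i] = interp_at(time, signal, ts)
    return out


@dataclass
class EmbeddedTrajectory:
    """Delay-embedded state trajectory built from a stack of normalized strides.

    ``values`` holds the 3*d-dimensional embedded states; ``stride_of_point``
    and ``segment_of_point`` locate each state's base sample, and
    ``segment_start``/``segment_length`` allow forward tracking within each
    contiguous segment.
    """

    values: np.ndarray          # (m, 3*d)
    stride_of_point: np.ndarray
    segment_of_point: np.ndarray
    offset_in_segment: np.ndarray
    segment_start: np.ndarray   # first row index of each segment in `values`
    segment_length: np.ndarray  # embedded rows per segment
    samples_per_stride: int = SAMPLES_PER_STRIDE
    copies: int = EMBED_COPIES
    delay: int = EMBED_DELAY
    n_strides: int = 0

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def delay_embed(stack: np.ndarray, segments: np.ndarray | None = None,
                copies: int = EMBED_COPIES, delay: int = EMBED_DELAY) -> EmbeddedTrajectory:
    """Time-delay embedding of a normalized stride stack.

    ``stack`` has shape ``(n_strides, samples_per_stride, n_channels)``;
    ``segments`` assigns each stride to a contiguous recording segment
    (default: one single segment).  The embedded state at normalized time t
    concatenates the base state at t with ``copies - 1`` copies delayed by
    ``delay, 2*delay, ...`` normalized timesteps (forward lookahead), so the
    dimension is ``n_channels * copies``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_strides, samples_per_stride, n_channels)")
    if copies < 1 or delay < 1:
        raise ValueError("copies must be >= 1 and delay >= 1")
    n_strides, sps, n_ch = stack.shape
    if segments is None:
        segments = np.zeros(n_strides, dtype=int)
    segments = np.asarray(segments)
    lookahead = (copies - 1) * delay

    values, stride_of, seg_of, offset = [], [], [], []
    seg_start, seg_len = [], []
    row = 0
    for seg in np.unique(segments):
        idx = np.flatnonzero(segments == seg)
        series = stack[idx].reshape(-1, n_ch)
        L = len(series)
        m = L - lookahead
        if m < 1:
            raise ValueError(f"segment {seg} too short for (d-1)*T = {lookahead} lookahead")
        emb = np.concatenate([series[j * delay: j * delay + m] for j in range(copies)],
                             axis=1)
        values.append(emb)
        base_strides = idx[np.arange(m) // sps]
        stride_of.append(base_strides)
        seg_of.append(np.full(m, seg))
        offset.append(np.arange(m))
        seg_start.append(row)
        seg_len.append(m)
        row += m
    return EmbeddedTrajectory(
        values=np.concatenate(values, axis=0),
        stride_of_point=np.concatenate(stride_of),
        segment_of_point=np.concatenate(seg_of),
        offset_in_segment=np.concatenate(offset),
        segment_start=np.asarray(seg_start),
        segment_length=np.asarray(seg_len),
        samples_per_stride=sps, copies=copies, delay=delay, n_strides=n_strides)


def _nearest_other_stride(emb: EmbeddedTrajectory, candidate_mask: np.ndarray,
                          chunk: int = 512) -> np.ndarray:
    """Index of each point's nearest neighbour originating in another stride.

    Candidates at exactly zero distance are excluded (guards duplicated
    strides under bootstrap resampling).  Returns -1 where no candidate
    exists.
    """
    V = emb.values
    m = len(V)
    cand_idx = np.flatnonzero(candidate_mask)
    if len(cand_idx) == 0:
        return np.full(m, -1)
    C = V[cand_idx]
    cand_stride = emb.stride_of_point[cand_idx]
    nn = np.full(m, -1)
    c_sq = np.einsum("ij,ij->i", C, C)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        block = V[lo:hi]
        d2 = np.maximum(
            np.einsum("ij,ij->i", block, block)[:, None] - 2.0 * block @ C.T + c_sq[None, :],
            0.0)
        same = emb.stride_of_point[lo:hi, None] == cand_stride[None, :]
        d2[same] = np.inf
        d2[d2 <= 1e-24] = np.inf
        j = np.argmin(d2, axis=1)
        ok = np.isfinite(d2[np.arange(hi - lo), j])
        nn[lo:hi][ok] = cand_idx[j[ok]]
    return nn


def max_lyapunov(emb: EmbeddedTrajectory, fit_steps: int = SAMPLES_PER_STRIDE,
                 stride_subset: np.ndarray | None = None, *,
                 subject: str = "", condition: str = "", regime: str = "steady",
                 return_curve: bool = False):
    """Short-term maximum Lyapunov exponent of an embedded stride trajectory.

    For every embedded point the nearest neighbour in *other* strides is
    found; the log Euclidean distance between the two forward trajectories is
    tracked at each subsequent normalized timestep (truncated at segment
    ends), averaged over points at each timestep, and an OLS line over the
    first ``fit_steps`` timesteps (one stride) gives the exponent in units of
    1 / normalized-stride-time-step.

    ``stride_subset`` (a possibly repeating array of stride ids) restricts
    reference points and neighbour candidates to those strides — the
    bootstrap resampling unit — while forward tracking stays on the original
    contiguous recording.
    """
    if emb.n_strides < 2:
        raise ValueError("need at least two strides")
    if stride_subset is None:
        ref_weight = np.ones(len(emb.values))
        candidate_mask = np.ones(len(emb.values), dtype=bool)
        n_strides_used = emb.n_strides
    else:
        stride_subset = np.asarray(stride_subset)
        counts = np.bincount(stride_subset, minlength=emb.n_strides)
        ref_weight = counts[emb.stride_of_point].astype(float)
        candidate_mask = ref_weight > 0
        n_strides_used = len(stride_subset)

    nn = _nearest_other_stride(emb, candidate_mask)
    refs = np.flatnonzero((nn >= 0) & (ref_weight > 0))
    if len(refs) == 0:
        raise ValueError("no usable nearest neighbours: all candidate strides are "
                         "duplicates at zero distance; review neighbour exclusion")
    w = ref_weight[refs]
    seg_end_ref = emb.segment_start[emb.segment_of_point[refs]] + \
        emb.segment_length[emb.segment_of_point[refs]]
    seg_end_nn = emb.segment_start[emb.segment_of_point[nn[refs]]] + \
        emb.segment_length[emb.segment_of_point[nn[refs]]]
    horizon = np.minimum(seg_end_ref - refs, seg_end_nn - nn[refs])

    V = emb.values
    curve = np.empty(fit_steps)
    counts = np.empty(fit_steps)
    a = refs.copy()
    b = nn[refs].copy()
    for j in range(fit_steps):
        alive = horizon > j
        if not alive.any():
            curve[j:] = np.nan
            counts[j:] = 0
            break
        diff = V[a[alive] + j] - V[b[alive] + j]
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        good = d > 0
        wj = w[alive][good]
        curve[j] = float(np.average(np.log(d[good]), weights=wj)) if good.any() else np.nan
        counts[j] = wj.sum() if good.any() else 0
    ok = np.isfinite(curve)
    if ok.sum() < 2:
        raise ValueError("divergence curve too short to fit")
    t = np.arange(fit_steps, dtype=float)[ok]
    slope = float(np.polyfit(t, curve[ok], 1)[0])
    score = MetricScore(subject, condition, "max_lyapunov", slope, regime, True,
                        n_strides_used)
    if return_curve:
        return score, curve
    return score


def lyapunov_strides_steady(stride_bounds_per_trial: list[list[tuple[float, float]]],
                            sections: int = 8, strides_per_section: int = 9
                            ) -> list[list[tuple[float, float]]]:
    """Select 144 strides as ``sections`` x ``strides_per_section`` from each of
    two unperturbed trials; returns contiguous groups (segments)."""
    if len(stride_bounds_per_trial) != 2:
        raise ValueError("steady Lyapunov selection needs exactly two unperturbed trials")
    groups = []
    for bounds in stride_bounds_per_trial:
        parts = np.array_split(np.arange(len(bounds)), sections)
        for part in parts:
            if len(part) < strides_per_section:
                raise ShortfallError(
                    f"section has {len(part)} strides, need {strides_per_section}")
            sel = part[:strides_per_section]
            groups.append([bounds[i] for i in sel])
    return groups


def lyapunov_strides_perturbed(stride_bounds: list[tuple[float, float]],
                               onsets: np.ndarray, strides_per_perturbation: int = 9,
                               onset_stride: int = 5) -> list[list[tuple[float, float]]]:
    """Nine strides per perturbation with the onset during the fifth stride."""
    starts = np.array([b[0] for b in stride_bounds])
    ends = np.array([b[1] for b in stride_bounds])
    groups = []
    for onset in np.sort(np.asarray(onsets)):
        inside = np.flatnonzero((starts <= onset) & (onset < ends))
        if len(inside) == 0:
            raise ShortfallError(f"no stride contains the onset at {onset:.2f} s")
        j = int(inside[0])
        lo = j - (onset_stride - 1)
        hi = lo + strides_per_perturbation
        if lo < 0 or hi > len(stride_bounds):
            raise ShortfallError(f"perturbation at {onset:.2f} s lacks surrounding strides")
        groups.append(stride_bounds[lo:hi])
    return groups


# ---------------------------------------------------------------------------
# margin of stability
# ---------------------------------------------------------------------------

def pendulum_natural_frequency(length: float, gravity: float = GRAVITY) -> float:
    if length <= 0:
        raise ValueError("pendulum length must be > 0")
    return float(np.sqrt(gravity / length))


def extrapolated_com(position: np.ndarray, velocity: np.ndarray,
                     length: float) -> np.ndarray:
    """Extrapolated CoM = position + velocity / omega0, omega0 = sqrt(g/l)."""
    return np.asarray(position) + np.asarray(velocity) / pendulum_natural_frequency(length)


def margin_of_stability(com: ComState, markers: dict[str, np.ndarray],
                        marker_time: np.ndarray, events: pd.DataFrame,
                        axis: str = "lateral", budget: int = STEP_BUDGET, *,
                        subject: str = "", condition: str = "", regime: str = "steady",
                        prefiltered: bool = False,
                        heel_strike_times: np.ndarray | None = None,
                        sides: np.ndarray | None = None) -> MetricScore:
    """Mean margin of stability over the first ``budget`` heel strikes.

    Per step the equivalent pendulum length is the ankle-marker-to-CoM
    distance at heel strike; the extrapolated CoM adds velocity / omega0; the
    value is the distance from the extrapolated CoM to the leading foot's
    fifth-metatarsal marker along the chosen axis, positive when the marker
    lies beyond the extrapolated CoM (toward the lateral or anterior
    boundary).  Higher values are read as worse balance.
    """
    if axis not in ("lateral", "anterior"):
        raise ValueError("axis must be 'lateral' or 'anterior'")
    need = ("L_ankle", "R_ankle", "L_metatarsal5", "R_metatarsal5")
    for name in need:
        if name not in markers:
            raise ValueError(f"marker {name!r} missing")
    rate = 1.0 / float(np.median(np.diff(marker_time)))
    filt = {}
    for name in need:
        arr = np.asarray(markers[name], dtype=float)
        filt[name] = arr if prefiltered else zero_lag_butterworth(
            arr, 4, FOOT_MARKER_CUTOFF_HZ, rate)

    if heel_strike_times is None:
        hs = valid_heel_strikes(events)
        heel_strike_times = hs["time_s"].to_numpy()
        sides = hs["side"].to_numpy()
    _require_budget(len(heel_strike_times), budget, "margin of stability",
                    subject, condition)
    values = []
    for t, side in zip(heel_strike_times[:budget], sides[:budget]):
        pfx = "L" if side == "left" else "R"
        ankle = interp_at(marker_time, filt[f"{pfx}_ankle"], t)[0]
        mt5 = interp_at(marker_time, filt[f"{pfx}_metatarsal5"], t)[0]
        pos = interp_at(com.time, com.position, t)[0]
        vel = interp_at(com.time, com.velocity, t)[0]
        length = float(np.linalg.norm(ankle - pos))
        if length <= 0:
            raise ValueError("pendulum length <= 0")
        xcom = extrapolated_com(pos, vel, length)
        if axis == "lateral":
            sgn = 1.0 if side == "left" else -1.0
            values.append(sgn * (mt5[1] - xcom[1]))
        else:
            values.append(mt5[0] - xcom[0])
    name = "lateral_margin_of_stability" if axis == "lateral" \
        else "anterior_margin_of_stability"
    return MetricScore(subject, condition, name, float(np.mean(values)), regime,
                       True, budget)


# ---------------------------------------------------------------------------
# CoM displacement after a perturbation
# ---------------------------------------------------------------------------

def com_displacement(com: ComState, events: pd.DataFrame,
                     perturbation_log: pd.DataFrame, *,
                     direction: str = "right", magnitude_pct_bw: float = 7.5,
                     onset_tolerance: float = 0.08,
                     subject: str = "", condition: str = "") -> MetricScore:
    """Mean ML CoM travel over one gait cycle for the two qualifying pulses.

    Qualifying perturbations are the low-magnitude (7.5 %BW) rightward ones;
    displacement is the ML CoM position at the next left-leg midstance minus
    the position at the onset midstance, projected on the perturbation
    direction (rightward = -y).
    """
    qual = perturbation_log[
        (perturbation_log["direction"] == direction)
        & (np.isclose(perturbation_log["magnitude_pct_bw"], magnitude_pct_bw))]
    if len(qual) < 2:
        raise ValueError(f"need at least two qualifying perturbations, found {len(qual)}")
    mid = find_midstance(events)
    left_mid = mid[mid["side"] == "left"]["time_s"].to_numpy()
    if len(left_mid) < 2:
        raise ValueError("not enough left-leg midstances detected")
    uy = {"left": 1.0, "right": -1.0, "forward": 0.0, "backward": 0.0}[direction]
    disps = []
    for onset in qual["onset_s"]:
        i = int(np.argmin(np.abs(left_mid - onset)))
        if abs(left_mid[i] - onset) > onset_tolerance:
            raise ValueError(f"no left midstance within {onset_tolerance * 1e3:.0f} ms "
                             f"of onset {onset:.2f} s")
        if i + 1 >= len(left_mid):
            raise ValueError(f"no left midstance after onset {onset:.2f} s")
        y0 = float(interp_at(com.time, com.position[:, 1], left_mid[i])[0])
        y1 = float(interp_at(com.time, com.position[:, 1], left_mid[i + 1])[0])
        disps.append((y1 - y0) * (uy if uy != 0 else 1.0))
    return MetricScore(subject, condition, "com_displacement", float(np.mean(disps)),
                       "perturbation_only", True, len(disps))
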