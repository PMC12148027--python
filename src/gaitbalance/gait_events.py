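"""Heel-strike / toe-off detection from CoP and GRF, stutter exclusion, midstance.

Heel strikes are detected post hoc from the resultant centre of pressure:
after a 6 Hz fourth-order zero-lag Butterworth filter, a candidate is raised
where the fore-aft CoP velocity rises above 0 m/s (laboratory frame) or
where the medial-lateral CoP speed rises above 0.7 m/s.  When both fire
within a pairing window (150 ms in perturbation trials, 200 ms in steady
walking) the earlier candidate is kept.  Per-belt vertical GRF provides an
independent event source via a 100 N rising/falling threshold after a 60 Hz
second-order zero-lag filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_io import (
    COP_CUTOFF_HZ,
    FOOT_MARKER_CUTOFF_HZ,
    GRF_CUTOFF_HZ,
    TrialTimeSeries,
    interp_at,
    zero_lag_butterworth,
)

__all__ = [
    "detect_heel_strikes_cop",
    "detect_events_force",
    "exclude_stutter_steps",
    "find_midstance",
    "merge_event_tables",
    "valid_heel_strikes",
    "detect_trial_events",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ("time_s", "type", "side", "source", "valid", "reason")

ML_VELOCITY_THRESHOLD = 0.7   # m/s
PAIRING_WINDOW_STEADY = 0.200  # s
PAIRING_WINDOW_PERTURBED = 0.150  # s
REFRACTORY_S = 0.100          # s, suppresses filter-ringing double crossings
STUTTER_HEIGHT_LIMIT = 0.2    # m, calcaneus must be below this at a heel strike


def _event_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            EVENT_COLUMNS, (float, str, str, str, bool, str))})
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _rising_crossings(x: np.ndarray, threshold: float, rate: float) -> np.ndarray:
    """Times where ``x`` crosses above ``threshold``, linearly interpolated."""
    below = x[:-1] <= threshold
    above = x[1:] > threshold
    idx = np.flatnonzero(below & above)
    frac = (threshold - x[idx]) / (x[idx + 1] - x[idx])
    return (idx + frac) / rate


def _falling_crossings(x: np.ndarray, threshold: float, rate: float) -> np.ndarray:
    above = x[:-1] >= threshold
    below = x[1:] < threshold
    idx = np.flatnonzero(above & below)
    frac = (x[idx] - threshold) / (x[idx] - x[idx + 1])
    return (idx + frac) / rate


def detect_heel_strikes_cop(cop_x: np.ndarray, cop_y: np.ndarray, rate: float,
                            trial_kind: str = "steady", *,
                            time: np.ndarray | None = None,
                            prefiltered: bool = False) -> pd.DataFrame:
    """Detect heel strikes from the resultant CoP trajectory.

    The 6 Hz zero-lag configuration is applied internally unless
    ``prefiltered=True`` asserts the caller already did.  If ``time`` is
    supplied it must be uniformly sampled at ``rate``.
    """
    if trial_kind not in ("steady", "perturbed"):
        raise ValueError(f"trial_kind must be 'steady' or 'perturbed', got {trial_kind!r}")
    cop_x = np.asarray(cop_x, dtype=float)
    cop_y = np.asarray(cop_y, dtype=float)
    if cop_x.shape != cop_y.shape or cop_x.ndim != 1:
        raise ValueError("cop_x and cop_y must be equal-length 1-D arrays")
    t0 = 0.0
    if time is not None:
        time = np.asarray(time, dtype=float)
        dt = np.diff(time)
        if np.any(np.abs(dt - 1.0 / rate) > 0.01 / rate):
            raise ValueError("CoP time vector is not uniformly sampled at the given rate")
        t0 = float(time[0])
    if not prefiltered:
        cop_x = zero_lag_butterworth(cop_x, 4, COP_CUTOFF_HZ, rate)
        cop_y = zero_lag_butterworth(cop_y, 4, COP_CUTOFF_HZ, rate)
    vx = np.gradient(cop_x, 1.0 / rate)
    vy = np.gradient(cop_y, 1.0 / rate)

    window = PAIRING_WINDOW_PERTURBED if trial_kind == "perturbed" else PAIRING_WINDOW_STEADY
    cand_fa = _rising_crossings(vx, 0.0, rate)
    cand_ml = _rising_crossings(np.abs(vy), ML_VELOCITY_THRESHOLD, rate)
    cand = np.sort(np.concatenate([cand_fa, cand_ml]))

    accepted: list[float] = []
    last = -np.inf
    for t in cand:
        if t - last < max(window, REFRACTORY_S):
            continue
        accepted.append(float(t))
        last = t

    rows = []
    n = len(cop_y)
    for t in accepted:
        i_before = int(np.clip(round((t - 0.05) * rate), 0, n - 1))
        i_after = int(np.clip(round((t + 0.15) * rate), 0, n - 1))
        side = "left" if cop_y[i_after] - cop_y[i_before] > 0 else "right"
        rows.append({"time_s": t + t0, "type": "heel_strike", "side": side,
                     "source": "cop", "valid": True, "reason": "none"})
    return _event_frame(rows)


def detect_events_force(fz_left: np.ndarray, fz_right: np.ndarray, rate: float, *,
                        threshold: float = 100.0,
                        time: np.ndarray | None = None,
                        prefiltered: bool = False) -> pd.DataFrame:
    """Per-belt heel strikes (rising 100 N crossing) and toe-offs (falling)."""
    t0 = float(time[0]) if time is not None else 0.0
    rows = []
    for side, fz in (("left", fz_left), ("right", fz_right)):
        fz = np.asarray(fz, dtype=float)
        if not prefiltered:
            fz = zero_lag_butterworth(fz, 2, GRF_CUTOFF_HZ, rate)
        for t in _rising_crossings(fz, threshold, rate):
            rows.append({"time_s": float(t) + t0, "type": "heel_strike", "side": side,
                         "source": "force", "valid": True, "reason": "none"})
        for t in _falling_crossings(fz, threshold, rate):
            rows.append({"time_s": float(t) + t0, "type": "toe_off", "side": side,
                         "source": "force", "valid": True, "reason": "none"})
    frame = _event_frame(rows)
    return frame.sort_values("time_s", kind="stable").reset_index(drop=True)


def merge_event_tables(*tables: pd.DataFrame) -> pd.DataFrame:
    merged = pd.concat(tables, ignore_index=True)
    return merged.sort_values("time_s", kind="stable").reset_index(drop=True)


def exclude_stutter_steps(events: pd.DataFrame, markers: dict[str, np.ndarray],
                          marker_time: np.ndarray, *,
                          height_limit: float = STUTTER_HEIGHT_LIMIT,
                          prefiltered: bool = False) -> pd.DataFrame:
    """Invalidate heel-strike candidates that are not proper steps.

    A candidate is rejected (``reason='stutter'``) when the foot in front at
    the candidate instant is the same foot as the previous valid heel strike
    — i.e. the swing foot was lifted but not placed past the contralateral
    leg — and (``reason='marker_height'``) when the candidate foot's
    calcaneus marker is at or above ``height_limit`` over the treadmill
    surface.  Toe-off events pass through unchanged.

    Sides of accepted candidates are reassigned from the front-foot marker:
    the CoP's ML transfer direction misidentifies the landing foot on
    crossed or very narrow steps, whereas the landing foot is reliably the
    one in front at the candidate instant.
    """
    for name in ("L_calcaneus", "R_calcaneus"):
        if name not in markers:
            raise ValueError(f"foot marker {name!r} missing")
    rate = 1.0 / float(np.median(np.diff(marker_time)))
    calc = {}
    for name in ("L_calcaneus", "R_calcaneus"):
        arr = np.asarray(markers[name], dtype=float)
        calc[name] = arr if prefiltered else zero_lag_butterworth(
            arr, 4, FOOT_MARKER_CUTOFF_HZ, rate)

    out = events.copy().sort_values("time_s", kind="stable").reset_index(drop=True)
    last_valid_side: str | None = None
    for i, row in out.iterrows():
        if row["type"] != "heel_strike" or not row["valid"]:
            continue
        t = row["time_s"]
        x_l = float(interp_at(marker_time, calc["L_calcaneus"][:, 0], t)[0])
        x_r = float(interp_at(marker_time, calc["R_calcaneus"][:, 0], t)[0])
        front = "left" if x_l > x_r else "right"
        front_marker = "L_calcaneus" if front == "left" else "R_calcaneus"
        z = float(interp_at(marker_time, calc[front_marker][:, 2], t)[0])
        if z >= height_limit:
            out.loc[i, ["valid", "reason"]] = [False, "marker_height"]
            continue
        if last_valid_side is not None and front == last_valid_side:
            out.loc[i, ["valid", "reason"]] = [False, "stutter"]
            continue
        out.loc[i, "side"] = front
        last_valid_side = front
    return out


def valid_heel_strikes(events: pd.DataFrame) -> pd.DataFrame:
    hs = events[(events["type"] == "heel_strike") & events["valid"]]
    return hs.sort_values("time_s", kind="stable").reset_index(drop=True)


def find_midstance(events: pd.DataFrame) -> pd.DataFrame:
    """Midstance = temporal midpoint of a foot's heel strike and its toe-off.

    One midstance per valid stance; stances without a subsequent ipsilateral
    toe-off (before the next ipsilateral heel strike) are skipped.
    """
    rows = []
    for side in ("left", "right"):
        hs = events[(events["type"] == "heel_strike") & events["valid"]
                    & (events["side"] == side)]["time_s"].to_numpy()
        to = events[(events["type"] == "toe_off") & events["valid"]
                    & (events["side"] == side)]["time_s"].to_numpy()
        hs = np.sort(hs)
        to = np.sort(to)
        for k, t in enumerate(hs):
            limit = hs[k + 1] if k + 1 < len(hs) else np.inf
            nxt = to[(to > t) & (to < limit)]
            if len(nxt) == 0:
                continue
            rows.append({"time_s": (t + nxt[0]) / 2.0, "side": side,
                         "heel_strike_s": t, "toe_off_s": nxt[0]})
    frame = pd.DataFrame(rows, columns=["time_s", "side", "heel_strike_s", "toe_off_s"])
    return frame.sort_values("time_s", kind="stable").reset_index(drop=True)


def detect_trial_events(trial: TrialTimeSeries) -> pd.DataFrame:
    """Full event pipeline for one trial: CoP heel strikes, force toe-offs,
    stutter exclusion.  Returns the merged event table."""
    kind = trial.meta.get("kind", "steady")
    rate = trial.force_rate
    hs = detect_heel_strikes_cop(trial.forces["cop_x"], trial.forces["cop_y"],
                                 rate, kind, time=trial.force_time)
    force_ev = detect_events_force(trial.forces["fz_left"], trial.forces["fz_right"],
                                   rate, time=trial.force_time)
    toe_offs = force_ev[force_ev["type"] == "toe_off"]
    merged = merge_event_tables(hs, toe_offs)
    return exclude_stutter_steps(merged, trial.markers, trial.marker_time)
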