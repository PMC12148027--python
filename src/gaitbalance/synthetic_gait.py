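"""Synthetic treadmill-gait cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of subjects walking at fixed treadmill speed under one
unimpaired and several impaired conditions, where impairments inflate
step-time variability, step-width variability, the residual noise of a
linear medial-lateral foot-placement law, and the divergence rate of upper
body motion.  Pelvis perturbation bouts follow the standard protocol: 16
force pulses (4 directions x 2 magnitudes, each twice, pseudorandom order),
300 ms long, 25-30 s apart, onset at left-leg midstance.

Every generated quantity that a pipeline stage later estimates is recorded
as ground truth: heel-strike / toe-off times and sides, per-step widths,
times and placements, the foot-placement coefficients and residual SD, the
injected divergence rate and per-perturbation centre-of-mass displacement.

All default magnitudes that the source protocol does not fix (baseline
means, SDs, impulse gains, marker geometry) are invented, collected in
module-level constants or the config, and documented as tunable in
docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BPoly

from .signal_io import TrialTimeSeries

__all__ = [
    "ImpairmentMultipliers",
    "InterSubjectSd",
    "SyntheticCohortConfig",
    "SubjectParams",
    "TrialGroundTruth",
    "SyntheticTrial",
    "SyntheticDataset",
    "generate_cohort",
    "generate_trial",
    "draw_subject_params",
    "make_divergent_stride_stack",
    "make_periodic_stride_stack",
]

# --- foot-placement law (the linear model the analysis fits) --------------
# placement = POS_GAIN * (CoM y rel. stance calcaneus at midstance)
#           + VEL_GAIN * (lab-frame CoM y-velocity at midstance) + residual
PLACEMENT_POS_GAIN = 1.2      # dimensionless
PLACEMENT_VEL_GAIN = 0.30     # s
STATE_SPLIT = 0.55            # fraction of the placement signal carried by position
STATE_EXTRA_SD = 0.004        # m, independent spread that keeps the regressors full rank

# --- gait geometry (invented, physiologically plausible) -------------------
DOUBLE_SUPPORT_S = 0.12
HEEL_HEIGHT = 0.02            # m, calcaneus marker height during stance
SWING_PEAK_HEIGHT = 0.13      # m, added mid-swing
FOOT_PROGRESSION = 0.18       # m, heel-to-toe CoP travel during stance
STEP_TIME_ASYMMETRY = 0.02    # s, left-minus-right step-time offset
GRF_RAMP_S = 0.09             # s, loading / unloading ramp of vertical GRF
# The unloading ramp is shifted so that the 100 N falling crossing of the
# plateau-scaled smoothstep lands at the nominal toe-off instant.
TOE_OFF_FORCE_SHIFT_S = 0.022
# CoP weight transfer: logistic centred this long after heel strike with this
# time constant.  Chosen so the 6 Hz zero-lag-filtered fore-aft CoP velocity
# crosses 0 m/s at the nominal footfall instant (see docs/methods.md).
TRANSFER_CENTER_S = 0.090
TRANSFER_TAU_S = 0.030

PERTURBATION_RISE_S = 0.30    # velocity impulse duration = pulse duration
PERTURBATION_DECAY_S = 0.80   # recovery time constant, ~3 steps to baseline
LORENZ_LAMBDA = 0.9056        # largest Lyapunov exponent of the canonical Lorenz system

_DIRECTIONS = ("forward", "backward", "left", "right")
_DIR_UNIT = {"forward": (1.0, 0.0), "backward": (-1.0, 0.0),
             "left": (0.0, 1.0), "right": (0.0, -1.0)}


@dataclass(frozen=True)
class ImpairmentMultipliers:
    """Multiplicative inflation an impairment applies to a subject's baseline."""

    step_width_sd: float = 1.0
    step_time_sd: float = 1.0
    placement_sd: float = 1.0
    divergence: float = 1.0

    def validate(self, name: str) -> None:
        for fld in ("step_width_sd", "step_time_sd", "placement_sd", "divergence"):
            if not getattr(self, fld) > 0:
                raise ValueError(f"impairment_multipliers[{name!r}].{fld} must be > 0")


@dataclass(frozen=True)
class InterSubjectSd:
    """Spread of baseline parameters across subjects (unrelated to impairment)."""

    mean_step_width: float = 0.020   # m
    mean_step_time: float = 0.030    # s
    step_width_sd: float = 0.003     # m
    step_time_sd: float = 0.003      # s
    placement_sd: float = 0.0015     # m
    divergence_rate: float = 0.001   # 1 / normalized timestep


def _default_multipliers() -> dict[str, ImpairmentMultipliers]:
    # Averages across impairments are ~1.5, matching the observed ~53-54%
    # inflation of step-time/step-width variability; the per-condition split
    # is invented (jets inject foot-placement noise most directly).
    return {
        "normal": ImpairmentMultipliers(),
        "braces": ImpairmentMultipliers(1.45, 1.45, 1.30, 1.20),
        "eyes_blocked": ImpairmentMultipliers(1.50, 1.55, 1.45, 1.25),
        "jets": ImpairmentMultipliers(1.65, 1.60, 1.80, 1.30),
    }


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 10
    conditions: tuple[str, ...] = ("normal", "braces", "eyes_blocked", "jets")
    unimpaired_condition: str = "normal"
    impairment_multipliers: dict[str, ImpairmentMultipliers] = field(
        default_factory=_default_multipliers)
    inter_subject_sd: InterSubjectSd = field(default_factory=InterSubjectSd)
    mean_step_width: float = 0.12       # m
    mean_step_time: float = 0.55        # s
    step_width_sd: float = 0.015        # m
    step_time_sd: float = 0.015         # s
    placement_sd: float = 0.009         # m (residual of the placement law)
    divergence_rate: float = 0.012      # 1 / normalized timestep
    treadmill_speed: float = 1.25       # m/s
    steady_trial_duration: float = 180.0  # s
    n_perturbations: int = 16
    perturbation_magnitudes: tuple[float, float] = (7.5, 15.0)  # % bodyweight
    perturbation_duration: float = 0.30   # s
    perturbation_directions: tuple[str, ...] = _DIRECTIONS
    perturbation_spacing: tuple[float, float] = (25.0, 30.0)    # s, uniform
    perturbation_response_gain: float = 0.05  # m CoM excursion per 7.5 %BW pulse
    marker_rate: float = 100.0
    force_rate: float = 1000.0
    variability_drift_per_min: float = 0.0  # fractional drift of sigmas, learning effects
    inject_stutters: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.unimpaired_condition not in self.conditions:
            raise ValueError("conditions must include the unimpaired condition "
                             f"{self.unimpaired_condition!r}")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("conditions must be unique")
        for cond in self.conditions:
            if cond not in self.impairment_multipliers:
                raise ValueError(f"impairment_multipliers missing condition {cond!r}")
            self.impairment_multipliers[cond].validate(cond)
        for fld in ("mean_step_width", "mean_step_time", "step_width_sd",
                    "step_time_sd", "placement_sd", "divergence_rate",
                    "treadmill_speed", "marker_rate", "force_rate",
                    "steady_trial_duration", "perturbation_duration",
                    "perturbation_response_gain"):
            if not getattr(self, fld) > 0:
                raise ValueError(f"{fld} must be > 0")
        if not self.placement_sd < self.step_width_sd:
            raise ValueError("placement_sd must be < step_width_sd: step-width "
                             "variance is residual variance plus state-driven variance")
        lo, hi = self.perturbation_spacing
        if not 0 < lo <= hi:
            raise ValueError("perturbation_spacing must satisfy 0 < lo <= hi")
        if self.n_perturbations % (2 * len(self.perturbation_directions)) and \
                self.n_perturbations != 0:
            # 8 unique types, each an equal number of times
            raise ValueError("n_perturbations must be a multiple of the number of "
                             "direction x magnitude types")


@dataclass(frozen=True)
class SubjectParams:
    """One subject's baseline, drawn once and shared across conditions."""

    subject: str
    mean_step_width: float
    mean_step_time: float
    step_width_sd: float
    step_time_sd: float
    placement_sd: float
    divergence_rate: float
    mass: float
    com_height: float

    def under(self, mult: ImpairmentMultipliers) -> "SubjectParams":
        sw = self.step_width_sd * mult.step_width_sd
        fp = min(self.placement_sd * mult.placement_sd, 0.9 * sw)
        return replace(self, step_width_sd=sw,
                       step_time_sd=self.step_time_sd * mult.step_time_sd,
                       placement_sd=fp,
                       divergence_rate=self.divergence_rate * mult.divergence)


@dataclass
class TrialGroundTruth:
    heel_strike_times: np.ndarray      # (n_steps,) s, strictly increasing
    sides: np.ndarray                  # (n_steps,) 'left'/'right', alternating
    toe_off_times: np.ndarray          # (n_steps,) s, toe-off of the foot that struck
    midstance_times: np.ndarray        # (n_steps,) s (NaN where undefined)
    step_widths: np.ndarray            # (n_steps,) m signed, NaN for first step
    step_times: np.ndarray             # (n_steps,) s, NaN for first step
    placements: np.ndarray             # (n_steps,) m swing-rel-stance, NaN for first
    com_rel_pos: np.ndarray            # (n_steps,) m, state feeding placement k (NaN first)
    com_vel: np.ndarray                # (n_steps,) m/s, same alignment
    placement_coefficients: tuple[float, float, float]  # (intercept, pos gain, vel gain)
    step_width_sd: float
    step_time_sd: float
    placement_sd: float
    divergence_rate: float
    perturbations: pd.DataFrame | None = None   # onset_s, direction, magnitude, ...
    com_displacements: pd.DataFrame | None = None
    stutter_times: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SyntheticTrial:
    trial: TrialTimeSeries
    truth: TrialGroundTruth


@dataclass
class SyntheticDataset:
    config: SyntheticCohortConfig
    subjects: dict[str, SubjectParams]
    trials: dict[tuple[str, str], list[SyntheticTrial]]

    def group(self, subject: str, condition: str) -> list[SyntheticTrial]:
        return self.trials[(subject, condition)]


# ---------------------------------------------------------------------------
# random draws
# ---------------------------------------------------------------------------

def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw parameterised by its own mean and SD (keeps sigmas > 0)."""
    if sd == 0:
        return mean
    var_ln = math.log(1.0 + (sd / mean) ** 2)
    mu_ln = math.log(mean) - var_ln / 2.0
    return float(rng.lognormal(mu_ln, math.sqrt(var_ln)))


def draw_subject_params(config: SyntheticCohortConfig, subject_index: int) -> SubjectParams:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, subject_index, 101)))
    iss = config.inter_subject_sd
    width = max(0.06, rng.normal(config.mean_step_width, iss.mean_step_width))
    step_time = float(np.clip(rng.normal(config.mean_step_time, iss.mean_step_time),
                              0.40, 0.80))
    sw_sd = _lognormal(rng, config.step_width_sd, iss.step_width_sd)
    st_sd = _lognormal(rng, config.step_time_sd, iss.step_time_sd)
    fp_sd = min(_lognormal(rng, config.placement_sd, iss.placement_sd), 0.8 * sw_sd)
    div = _lognormal(rng, config.divergence_rate, iss.divergence_rate)
    mass = max(45.0, rng.normal(68.0, 13.0))
    return SubjectParams(subject=f"S{subject_index + 1:02d}",
                         mean_step_width=width, mean_step_time=step_time,
                         step_width_sd=sw_sd, step_time_sd=st_sd, placement_sd=fp_sd,
                         divergence_rate=div, mass=mass, com_height=0.95)


# ---------------------------------------------------------------------------
# perturbation schedule and CoM impulse response
# ---------------------------------------------------------------------------

def _schedule_perturbations(config: SyntheticCohortConfig, rng: np.random.Generator,
                            left_midstances: np.ndarray,
                            stride_margin: float) -> pd.DataFrame:
    """Pseudorandom 8-type x 2 schedule with onsets at left-leg midstance.

    Each onset is the first left midstance at or after the requested time
    (like a midstance-triggered controller).  Requested gaps are uniform on
    ``[lo, hi - stride_margin]`` so that realized inter-onset gaps stay
    within the stated ``[lo, hi]`` window after snapping.
    """
    n_types = 2 * len(config.perturbation_directions)
    reps = config.n_perturbations // n_types
    types = [(d, m) for d in config.perturbation_directions
             for m in config.perturbation_magnitudes] * reps
    order = rng.permutation(len(types))
    lo, hi = config.perturbation_spacing
    hi_eff = max(lo + 0.1, hi - stride_margin)

    def snap_forward(t: float) -> float:
        later = left_midstances[left_midstances >= t]
        if not len(later):
            raise ValueError("trial too short to place all perturbations")
        return float(later[0])

    onsets = [snap_forward(12.0 + rng.uniform(0.0, 3.0))]
    for _ in range(config.n_perturbations - 1):
        onsets.append(snap_forward(onsets[-1] + rng.uniform(lo, hi_eff)))
    rows = [{"onset_s": onsets[i],
             "direction": types[order[i]][0],
             "magnitude_pct_bw": float(types[order[i]][1]),
             "duration_s": config.perturbation_duration}
            for i in range(config.n_perturbations)]
    return pd.DataFrame(rows)


def _bump_shape(tau: np.ndarray) -> np.ndarray:
    """Unit CoM excursion: smooth rise over the pulse, exponential recovery."""
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < PERTURBATION_RISE_S)
    u = tau[rising] / PERTURBATION_RISE_S
    out[rising] = 3 * u ** 2 - 2 * u ** 3
    after = tau >= PERTURBATION_RISE_S
    out[after] = np.exp(-(tau[after] - PERTURBATION_RISE_S) / PERTURBATION_DECAY_S)
    return out


def _bump_shape_deriv(tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < PERTURBATION_RISE_S)
    u = tau[rising] / PERTURBATION_RISE_S
    out[rising] = (6 * u - 6 * u ** 2) / PERTURBATION_RISE_S
    after = tau >= PERTURBATION_RISE_S
    out[after] = -np.exp(-(tau[after] - PERTURBATION_RISE_S) / PERTURBATION_DECAY_S) \
        / PERTURBATION_DECAY_S
    return out


class _ComBump:
    """Sum of perturbation-induced CoM excursions, as a function of time."""

    def __init__(self, perturbations: pd.DataFrame | None, gain: float):
        self.events: list[tuple[float, float, float]] = []  # onset, amp_x, amp_y
        if perturbations is not None:
            for _, row in perturbations.iterrows():
                ux, uy = _DIR_UNIT[row["direction"]]
                amp = gain * row["magnitude_pct_bw"] / 7.5
                self.events.append((row["onset_s"], amp * ux, amp * uy))

    def eval(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        x = np.zeros_like(t)
        y = np.zeros_like(t)
        for onset, ax, ay in self.events:
            s = _bump_shape(t - onset)
            x += ax * s
            y += ay * s
        return x, y

    def eval_deriv(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, dtype=float)
        x = np.zeros_like(t)
        y = np.zeros_like(t)
        for onset, ax, ay in self.events:
            s = _bump_shape_deriv(t - onset)
            x += ax * s
            y += ay * s
        return x, y


# ---------------------------------------------------------------------------
# chaotic component of the C7 signal
# ---------------------------------------------------------------------------

def _lorenz_series(n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Fixed-step RK4 integration of the Lorenz system, standardised per axis.

    The largest Lyapunov exponent of the canonical system (sigma=10, rho=28,
    beta=8/3) is ~0.9056 per unit time, so sampling with time step ``dt``
    yields ~0.9056*dt per sample.
    """
    try:
        out = _lorenz_numba(n, dt, rng.uniform(-10, 10), rng.uniform(-10, 10),
                            rng.uniform(15, 35))
    except Exception:  # numba unavailable or compilation failure
        out = _lorenz_python(n, dt, rng.uniform(-10, 10), rng.uniform(-10, 10),
                             rng.uniform(15, 35))
    out = out - out.mean(axis=0)
    sd = out.std(axis=0)
    sd[sd == 0] = 1.0
    return out / sd


def _lorenz_python(n: int, dt: float, x: float, y: float, z: float) -> np.ndarray:
    out = np.empty((n, 3))

    def deriv(x, y, z):
        return 10.0 * (y - x), x * (28.0 - z) - y, x * y - 8.0 / 3.0 * z

    # burn-in onto the attractor
    for _ in range(500):
        k1 = deriv(x, y, z)
        k2 = deriv(x + dt / 2 * k1[0], y + dt / 2 * k1[1], z + dt / 2 * k1[2])
        k3 = deriv(x + dt / 2 * k2[0], y + dt / 2 * k2[1], z + dt / 2 * k2[2])
        k4 = deriv(x + dt * k3[0], y + dt * k3[1], z + dt * k3[2])
        x += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        z += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    for i in range(n):
        out[i] = (x, y, z)
        k1 = deriv(x, y, z)
        k2 = deriv(x + dt / 2 * k1[0], y + dt / 2 * k1[1], z + dt / 2 * k1[2])
        k3 = deriv(x + dt / 2 * k2[0], y + dt / 2 * k2[1], z + dt / 2 * k2[2])
        k4 = deriv(x + dt * k3[0], y + dt * k3[1], z + dt * k3[2])
        x += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        z += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    return out


try:  # accelerate the sequential integration when numba is available
    from numba import njit as _njit

    @_njit(cache=False)
    def _lorenz_numba(n, dt, x, y, z):  # pragma: no cover - thin numeric kernel
        out = np.empty((n, 3))
        for i in range(-500, n):
            if i >= 0:
                out[i, 0] = x
                out[i, 1] = y
                out[i, 2] = z
            k1x = 10.0 * (y - x); k1y = x * (28.0 - z) - y; k1z = x * y - 8.0 / 3.0 * z
            ax = x + dt / 2 * k1x; ay = y + dt / 2 * k1y; az = z + dt / 2 * k1z
            k2x = 10.0 * (ay - ax); k2y = ax * (28.0 - az) - ay; k2z = ax * ay - 8.0 / 3.0 * az
            bx = x + dt / 2 * k2x; by = y + dt / 2 * k2y; bz = z + dt / 2 * k2z
            k3x = 10.0 * (by - bx); k3y = bx * (28.0 - bz) - by; k3z = bx * by - 8.0 / 3.0 * bz
            cx = x + dt * k3x; cy = y + dt * k3y; cz = z + dt * k3z
            k4x = 10.0 * (cy - cx); k4y = cx * (28.0 - cz) - cy; k4z = cx * cy - 8.0 / 3.0 * cz
            x += dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            y += dt / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
            z += dt / 6 * (k1z + 2 * k2z + 2 * k3z + k4z)
        return out
except ImportError:  # pragma: no cover
    def _lorenz_numba(n, dt, x, y, z):
        raise RuntimeError("numba unavailable")


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3 * u ** 2 - 2 * u ** 3


def generate_trial(params: SubjectParams, config: SyntheticCohortConfig, kind: str,
                   duration: float | None = None,
                   seed: int | tuple | np.random.SeedSequence = 0) -> SyntheticTrial:
    """Generate one trial (``steady`` or ``perturbed``) for one subject-condition.

    ``params`` already carries the condition's multipliers (see
    ``SubjectParams.under``).  ``duration`` applies to steady trials; the
    duration of a perturbed trial follows from its schedule (last onset plus
    a 15 s tail, with a >=12 s lead-in, so every onset is covered from 10 s
    before to 11 s after).
    """
    if kind not in ("steady", "perturbed"):
        raise ValueError(f"kind must be 'steady' or 'perturbed', got {kind!r}")
    for name in ("mean_step_width", "mean_step_time", "step_width_sd",
                 "step_time_sd", "placement_sd", "divergence_rate"):
        if not np.isfinite(getattr(params, name)):
            raise ValueError(f"subject parameter {name} is not finite")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    perturbations = None
    if kind == "perturbed" and config.n_perturbations > 0:
        # provisional upper bound; the trial is trimmed to the last onset + 15 s
        duration = 15.0 + config.n_perturbations * config.perturbation_spacing[1] + 15.0
    elif duration is None:
        duration = config.steady_trial_duration
    if duration <= 4.0 * params.mean_step_time:
        raise ValueError("trial duration must exceed two strides")

    # -- step skeleton -------------------------------------------------------
    t0, tail = 2.0, 1.5
    times, sides, dts = [t0], [0], [np.nan]  # side 0 = left, 1 = right
    drift = config.variability_drift_per_min
    while True:
        k = len(times)
        side = k % 2
        scale = max(0.1, 1.0 + drift * times[-1] / 60.0)
        asym = STEP_TIME_ASYMMETRY / 2.0 * (1 if side == 0 else -1)
        dt = params.mean_step_time + asym + scale * params.step_time_sd * rng.standard_normal()
        dt = max(dt, 0.25)
        t_next = times[-1] + dt
        if t_next > duration - tail:
            break
        times.append(t_next)
        sides.append(side)
        dts.append(dt)
    t_hs = np.asarray(times)
    sides = np.asarray(sides)
    step_times = np.asarray(dts)
    n = len(t_hs)
    if n < 6:
        raise ValueError("trial too short: fewer than six steps generated")

    t_to = np.full(n, np.nan)
    t_to[:-1] = t_hs[1:] + DOUBLE_SUPPORT_S
    t_mid = (t_hs + t_to) / 2.0

    # schedule perturbations at left-leg midstances, then trim the trial
    if kind == "perturbed" and config.n_perturbations > 0:
        left_mid = t_mid[(sides == 0) & np.isfinite(t_mid)]
        stride_margin = 2.0 * (params.mean_step_time + STEP_TIME_ASYMMETRY) \
            + 10.0 * params.step_time_sd
        perturbations = _schedule_perturbations(config, rng, left_mid, stride_margin)
        duration = float(perturbations["onset_s"].iloc[-1] + 15.0)
        keep = t_hs <= duration - tail
        t_hs, sides, step_times = t_hs[keep], sides[keep], step_times[keep]
        n = len(t_hs)
        t_to = np.full(n, np.nan)
        t_to[:-1] = t_hs[1:] + DOUBLE_SUPPORT_S
        t_mid = (t_hs + t_to) / 2.0
    bump = _ComBump(perturbations, config.perturbation_response_gain)

    # -- lateral placements via the linear law (exact by construction) -------
    sgn = np.where(sides == 0, 1.0, -1.0)        # landing left -> +y placement
    scale_t = np.maximum(0.1, 1.0 + drift * t_hs / 60.0)
    sigma_q = math.sqrt(max(params.step_width_sd ** 2 - params.placement_sd ** 2, 1e-12))
    q = sgn * params.mean_step_width + scale_t * sigma_q * rng.standard_normal(n)
    eps = scale_t * params.placement_sd * rng.standard_normal(n)
    z_extra = STATE_EXTRA_SD * rng.standard_normal(n)
    b, c = PLACEMENT_POS_GAIN, PLACEMENT_VEL_GAIN
    # state at the midstance preceding heel strike k (stance foot = foot k-1)
    rel_base = STATE_SPLIT * q / b + z_extra
    vel_base = (1.0 - STATE_SPLIT) * q / c - (b / c) * z_extra
    m_prev = np.concatenate([[np.nan], t_mid[:-1]])
    bump_y_mid = np.zeros(n)
    bump_vy_mid = np.zeros(n)
    finite_prev = np.isfinite(m_prev)
    if bump.events:
        _, bump_y_mid[finite_prev] = bump.eval(m_prev[finite_prev])
        _, bump_vy_mid[finite_prev] = bump.eval_deriv(m_prev[finite_prev])
    rel = rel_base + bump_y_mid
    vel = vel_base + bump_vy_mid
    placements = b * rel + c * vel + eps         # = q + eps (+ perturbation response)
    placements[0] = np.nan

    foot_y = np.empty(n)
    foot_y[0] = sgn[0] * params.mean_step_width / 2.0
    for k in range(1, n):
        foot_y[k] = foot_y[k - 1] + placements[k]

    widths = np.full(n, np.nan)
    widths[1:] = sgn[1:] * placements[1:]

    # CoM lateral knots: base spline carries the steady-state dynamics; the
    # perturbation bump is added analytically on top, consistent with the
    # states fed into the placement law above.
    knot_t = t_mid[:-1]
    knot_y = foot_y[:-1] + rel_base[1:]
    knot_v = vel_base[1:]
    # C2 quintic through (position, velocity, smooth acceleration) at each
    # midstance: a merely C1 spline has acceleration jumps at the knots, and
    # the 25 Hz zero-lag filter in the measurement chain rounds the resulting
    # velocity corners exactly where the placement model samples the state.
    knot_a = np.gradient(knot_v, knot_t)
    # rest-state end knots extend coverage over the whole trial so edge
    # midstances keep their exact prescribed states
    ext_t = np.concatenate([[0.0], knot_t, [duration + 0.1]])
    ext = np.vstack([[knot_y[0], 0.0, 0.0],
                     np.column_stack([knot_y, knot_v, knot_a]),
                     [knot_y[-1], 0.0, 0.0]])
    spline_y = BPoly.from_derivatives(ext_t, ext)

    # -- step length geometry -------------------------------------------------
    step_len = config.treadmill_speed * params.mean_step_time
    x_land = step_len / 2.0

    # -- marker channels ------------------------------------------------------
    mt = np.arange(0.0, duration, 1.0 / config.marker_rate)
    stride_s = 2.0 * params.mean_step_time

    com = np.empty((len(mt), 3))
    bx, by = bump.eval(mt)
    com[:, 0] = 0.02 * np.sin(2 * np.pi * mt / params.mean_step_time) + bx
    com[:, 1] = spline_y(mt) + by
    com[:, 2] = params.com_height + 0.015 * np.cos(2 * np.pi * mt / params.mean_step_time)

    feet = {}
    for side_idx, side_name in ((0, "L"), (1, "R")):
        idx = np.flatnonzero(sides == side_idx)
        xs = np.full(len(mt), x_land - config.treadmill_speed * 0.2)
        ys = np.full(len(mt), foot_y[idx[0]])
        zs = np.full(len(mt), HEEL_HEIGHT)
        for j, k in enumerate(idx):
            hs, to = t_hs[k], t_to[k]
            if not np.isfinite(to):
                to = min(t_hs[k] + 2 * params.mean_step_time, duration)
            i0, i1 = np.searchsorted(mt, [hs, to])
            seg = mt[i0:i1]
            xs[i0:i1] = x_land - config.treadmill_speed * (seg - hs)
            ys[i0:i1] = foot_y[k]
            zs[i0:i1] = HEEL_HEIGHT
            # swing to the next ipsilateral heel strike
            if j + 1 < len(idx):
                k2 = idx[j + 1]
                hs2 = t_hs[k2]
                i2 = np.searchsorted(mt, hs2)
                seg = mt[i1:i2]
                if len(seg):
                    u = (seg - to) / max(hs2 - to, 1e-6)
                    s = _smoothstep(u)
                    x_to = x_land - config.treadmill_speed * (to - hs)
                    xs[i1:i2] = x_to + (x_land - x_to) * s
                    ys[i1:i2] = foot_y[k] + (foot_y[k2] - foot_y[k]) * s
                    zs[i1:i2] = HEEL_HEIGHT + SWING_PEAK_HEIGHT * np.sin(np.pi * np.clip(u, 0, 1))
                xs[i2:] = x_land
                ys[i2:] = foot_y[k2]
                zs[i2:] = HEEL_HEIGHT
            else:
                xs[i1:] = x_land - config.treadmill_speed * (to - hs)
                ys[i1:] = foot_y[k]
                zs[i1:] = HEEL_HEIGHT
        xs[:np.searchsorted(mt, t_hs[idx[0]])] = x_land
        lat = 0.03 if side_idx == 0 else -0.03
        feet[f"{side_name}_calcaneus"] = np.column_stack([xs, ys, zs])
        feet[f"{side_name}_metatarsal5"] = np.column_stack([xs + 0.15, ys + lat, zs])
        feet[f"{side_name}_ankle"] = np.column_stack([xs + 0.05, ys, zs + 0.07])

    pelvis = {}
    for name, (ox, oy) in (("LASI", (0.10, 0.12)), ("RASI", (0.10, -0.12)),
                           ("LPSI", (-0.10, 0.12)), ("RPSI", (-0.10, -0.12))):
        pelvis[name] = com + np.array([ox, oy, 0.0])

    # C7: CoM motion + stride-periodic component + chaotic component whose
    # divergence rate is the condition's ground truth.
    lam_per_s = params.divergence_rate * 100.0 / stride_s
    dt_lorenz = lam_per_s / LORENZ_LAMBDA / config.marker_rate
    chaos = _lorenz_series(len(mt), dt_lorenz, rng) * 0.02
    phase = 2 * np.pi * mt / stride_s
    periodic = np.column_stack([0.010 * np.sin(2 * phase + 0.7),
                                0.015 * np.sin(phase),
                                0.010 * np.cos(2 * phase)])
    c7 = com + np.array([-0.05, 0.0, 0.70]) + periodic + chaos

    markers = {**feet, **pelvis, "C7": c7}

    # -- force-plate channels -------------------------------------------------
    ft = np.arange(0.0, duration, 1.0 / config.force_rate)
    fz = {0: np.zeros(len(ft)), 1: np.zeros(len(ft))}
    f_plateau = params.mass * 9.81 * 1.02
    for k in range(n):
        hs, to = t_hs[k], t_to[k]
        if not np.isfinite(to):
            to = min(hs + 1.5 * params.mean_step_time, duration - 1e-3)
        to_eff = to + TOE_OFF_FORCE_SHIFT_S
        i0, i1 = np.searchsorted(ft, [hs, to_eff])
        seg = ft[i0:i1]
        up = _smoothstep((seg - hs) / GRF_RAMP_S)
        down = _smoothstep((to_eff - seg) / GRF_RAMP_S)
        mid = 1.0 + 0.08 * np.sin(np.pi * (seg - hs) / max(to_eff - hs, 1e-6))
        fz[sides[k]][i0:i1] = np.maximum(fz[sides[k]][i0:i1], f_plateau * up * down * mid)

    # Designed resultant CoP: per-stance track with logistic weight transfer.
    # The track slope is constant (belt speed minus heel-to-toe progression)
    # and the transfer jump amplitude is decoupled from the individual step
    # time by a mean-reverting recursion of the track start position, so the
    # filtered-CoP event detector sees the same local signal shape at every
    # heel strike and step-time estimates stay undistorted.
    cop_x = np.empty(len(ft))
    cop_y = np.empty(len(ft))
    v_cop = config.treadmill_speed - FOOT_PROGRESSION / \
        (params.mean_step_time + DOUBLE_SUPPORT_S)
    x_start = np.empty(n)
    x_start[0] = x_land
    jump = v_cop * params.mean_step_time
    for k in range(1, n):
        x_old_at_hs = x_start[k - 1] - v_cop * (t_hs[k] - t_hs[k - 1])
        x_start[k] = x_old_at_hs + jump - 0.2 * (x_start[k - 1] - x_land)

    def foot_cop(k: int, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = x_start[k] - v_cop * (t - t_hs[k])
        return x, np.full_like(t, foot_y[k])

    centres = t_hs + TRANSFER_CENTER_S
    half = 6.0 * TRANSFER_TAU_S
    i_prev = np.searchsorted(ft, centres[0] + half)
    x0, y0 = foot_cop(0, ft[:i_prev])
    cop_x[:i_prev], cop_y[:i_prev] = x0, y0
    for k in range(1, n + 1):
        start = i_prev
        if k < n:
            i_tr0 = np.searchsorted(ft, centres[k] - half)
            i_tr1 = np.searchsorted(ft, centres[k] + half)
        else:
            i_tr0 = i_tr1 = len(ft)
        seg = ft[start:i_tr0]
        x_own, y_own = foot_cop(k - 1, seg)
        cop_x[start:i_tr0], cop_y[start:i_tr0] = x_own, y_own
        if k < n and i_tr1 > i_tr0:
            seg = ft[i_tr0:i_tr1]
            g = 1.0 / (1.0 + np.exp(-(seg - centres[k]) / TRANSFER_TAU_S))
            xo, yo = foot_cop(k - 1, seg)
            xn, yn = foot_cop(k, seg)
            cop_x[i_tr0:i_tr1] = (1 - g) * xo + g * xn
            cop_y[i_tr0:i_tr1] = (1 - g) * yo + g * yn
        i_prev = i_tr1

    # -- optional labelled stutter transients ---------------------------------
    stutter_times = np.empty(0)
    if config.inject_stutters and perturbations is not None and len(perturbations):
        chosen = []
        for _, row in perturbations.iterrows():
            if row["magnitude_pct_bw"] < max(config.perturbation_magnitudes):
                continue
            if row["direction"] not in ("left", "right"):
                continue
            k = np.searchsorted(t_hs, row["onset_s"] + 0.3)
            if k >= n - 2:
                continue
            t_s = t_hs[k] + 0.25  # shortly after a real heel strike: that foot
            chosen.append((t_s, sgn[k]))  # is still in front, so this is a stutter
        for t_s, sg in chosen:
            i0 = np.searchsorted(ft, t_s)
            i1 = np.searchsorted(ft, t_s + 0.45)
            seg = ft[i0:i1]
            rise = _smoothstep((seg - t_s) / 0.06)
            fall = np.exp(-np.maximum(seg - t_s - 0.06, 0.0) / 0.10)
            pulse = rise * fall
            cop_x[i0:i1] += 0.10 * pulse
            cop_y[i0:i1] += 0.03 * sg * pulse  # ML motion toward the previous foot
        stutter_times = np.array([t for t, _ in chosen])

    pert_fx = np.zeros(len(ft))
    pert_fy = np.zeros(len(ft))
    if perturbations is not None:
        for _, row in perturbations.iterrows():
            ux, uy = _DIR_UNIT[row["direction"]]
            force = row["magnitude_pct_bw"] / 100.0 * params.mass * 9.81
            i0, i1 = np.searchsorted(ft, [row["onset_s"], row["onset_s"] + row["duration_s"]])
            seg = ft[i0:i1]
            env = _smoothstep((seg - row["onset_s"]) / 0.03) * \
                _smoothstep((row["onset_s"] + row["duration_s"] - seg) / 0.03)
            pert_fx[i0:i1] += force * ux * env
            pert_fy[i0:i1] += force * uy * env

    forces = {"fz_left": fz[0], "fz_right": fz[1], "cop_x": cop_x, "cop_y": cop_y,
              "pert_fx": pert_fx, "pert_fy": pert_fy}
    meta = {"subject": params.subject, "condition": "", "kind": kind,
            "treadmill_speed": config.treadmill_speed, "duration_s": float(duration),
            "mass_kg": float(params.mass)}
    trial = TrialTimeSeries(marker_time=mt, markers=markers, force_time=ft,
                            forces=forces, meta=meta)

    # -- per-perturbation CoM displacement ground truth ------------------------
    com_disp = None
    if perturbations is not None and len(perturbations):
        rows = []
        left_mid = t_mid[(sides == 0) & np.isfinite(t_mid)]
        y_of = lambda t: float(spline_y(t) + bump.eval(np.atleast_1d(t))[1][0])
        for _, row in perturbations.iterrows():
            m0 = row["onset_s"]
            later = left_mid[left_mid > m0 + 1e-9]
            if not len(later):
                continue
            m1 = later[0]
            dy = y_of(m1) - y_of(m0)
            ux, uy = _DIR_UNIT[row["direction"]]
            proj = dy * uy if uy != 0 else dy
            rows.append({"onset_s": m0, "direction": row["direction"],
                         "magnitude_pct_bw": row["magnitude_pct_bw"],
                         "next_left_midstance_s": m1,
                         "delta_y_m": dy, "projected_m": proj})
        com_disp = pd.DataFrame(rows)

    truth = TrialGroundTruth(
        heel_strike_times=t_hs,
        sides=np.where(sides == 0, "left", "right"),
        toe_off_times=t_to,
        midstance_times=t_mid,
        step_widths=widths,
        step_times=step_times,
        placements=placements,
        com_rel_pos=np.concatenate([[np.nan], rel[1:]]),
        com_vel=np.concatenate([[np.nan], vel[1:]]),
        placement_coefficients=(0.0, b, c),
        step_width_sd=params.step_width_sd,
        step_time_sd=params.step_time_sd,
        placement_sd=params.placement_sd,
        divergence_rate=params.divergence_rate,
        perturbations=perturbations,
        com_displacements=com_disp,
        stutter_times=stutter_times,
    )
    return SyntheticTrial(trial=trial, truth=truth)


def generate_cohort(config: SyntheticCohortConfig,
                    include_perturbation_bout: bool = True) -> SyntheticDataset:
    """Generate the full protocol for every subject x condition.

    Each group contains two steady-state trials and, unless
    ``include_perturbation_bout=False`` (useful when only steady-state
    metrics are needed; the full default cohort holds ~2.5 GB of signals),
    one perturbation bout between them.
    """
    config.validate()
    subjects = {p.subject: p
                for p in (draw_subject_params(config, i) for i in range(config.n_subjects))}
    trials: dict[tuple[str, str], list[SyntheticTrial]] = {}
    kinds = ["steady", "perturbed", "steady"] if include_perturbation_bout \
        else ["steady", "steady"]
    for si, (sid, sparams) in enumerate(subjects.items()):
        for ci, cond in enumerate(config.conditions):
            cparams = sparams.under(config.impairment_multipliers[cond])
            group = []
            for ti, kind in enumerate(kinds):
                st = generate_trial(cparams, config, kind,
                                    duration=config.steady_trial_duration,
                                    seed=(config.seed, si, ci, ti))
                st.trial.meta["condition"] = cond
                st.trial.meta["trial_index"] = ti
                group.append(st)
            trials[(sid, cond)] = group
    return SyntheticDataset(config=config, subjects=subjects, trials=trials)


# ---------------------------------------------------------------------------
# validation stacks for the divergence estimator
# ---------------------------------------------------------------------------

def make_divergent_stride_stack(lam: float, n_strides: int = 144,
                                strides_per_segment: int | None = None,
                                samples_per_stride: int = 100,
                                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stride stack with prescribed short-term divergence rate ``lam``.

    A scalar state follows a uniformly expanding fold map,
    ``x -> fold(exp(lam) * x + phi)`` with ``fold(z) = |z mod 2 - 1|`` (a
    continuous triangle reflection into [0, 1]; ``phi`` an irrational shift
    that keeps the invariant density near-uniform).  The map is continuous
    with |slope| = exp(lam) everywhere, so nearby trajectories separate
    exactly as ``d(t) = d(0) * exp(lam * t)`` between the rare fold events,
    and the state is observed linearly — the mean log-divergence curve is a
    straight line of slope ``lam``.  By default the 144 strides form one
    contiguous segment so divergence records rarely hit a segment end inside
    the one-stride fit window.

    Returns ``(stack, segments)`` with ``stack`` of shape
    ``(n_strides, samples_per_stride, 3)`` and ``segments`` the contiguous
    segment id of each stride.
    """
    rng = np.random.default_rng(seed)
    if strides_per_segment is None:
        strides_per_segment = n_strides
    if n_strides % strides_per_segment:
        raise ValueError("n_strides must be a multiple of strides_per_segment")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    n_segments = n_strides // strides_per_segment
    seg_len = strides_per_segment * samples_per_stride
    a = math.exp(lam)
    phi = 0.6180339887498949
    stack = np.empty((n_strides, samples_per_stride, 3))
    segments = np.repeat(np.arange(n_segments), strides_per_segment)
    for s in range(n_segments):
        x = float(rng.uniform(0.0, 1.0))
        states = np.empty(seg_len)
        for t in range(seg_len):
            states[t] = x
            x = abs(((a * x + phi) % 2.0) - 1.0)
        series = np.column_stack([states - 0.5,
                                  np.zeros_like(states),
                                  np.zeros_like(states)])
        for j in range(strides_per_segment):
            stack[s * strides_per_segment + j] = \
                series[j * samples_per_stride:(j + 1) * samples_per_stride]
    return stack, segments


def make_periodic_stride_stack(eps: float = 1e-6, n_strides: int = 144,
                               strides_per_segment: int = 9,
                               samples_per_stride: int = 100,
                               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Strictly periodic strides plus a tiny constant per-segment offset.

    Nearest-neighbour distances are then constant in time, so the divergence
    slope is ~0; ``eps`` sets the offset scale.
    """
    rng = np.random.default_rng(seed)
    if n_strides % strides_per_segment:
        raise ValueError("n_strides must be a multiple of strides_per_segment")
    n_segments = n_strides // strides_per_segment
    phase = 2 * np.pi * np.arange(samples_per_stride) / samples_per_stride
    base = np.column_stack([np.sin(phase), np.cos(phase), np.sin(2 * phase)])
    stack = np.empty((n_strides, samples_per_stride, 3))
    segments = np.repeat(np.arange(n_segments), strides_per_segment)
    for s in range(n_segments):
        offset = rng.normal(scale=eps, size=3)
        for j in range(strides_per_segment):
            stack[s * strides_per_segment + j] = base + offset
    return stack, segments
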