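"""Trial containers, zero-lag filtering, centre-of-mass estimation and table I/O.

Coordinate convention used throughout the package:

* ``x`` — fore-aft, positive forward (direction of progression),
* ``y`` — medial-lateral, positive toward the subject's left,
* ``z`` — vertical, positive up, zero at the treadmill surface.

Marker trajectories are sampled at the motion-capture rate (100 Hz by
default); ground-reaction-force and centre-of-pressure channels at the
force-plate rate (1000 Hz).  Both clocks share a common origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal

__all__ = [
    "TrialTimeSeries",
    "ComState",
    "zero_lag_butterworth",
    "estimate_com",
    "interp_at",
    "write_trial",
    "read_trial",
    "write_perturbation_log",
    "read_perturbation_log",
    "COP_CUTOFF_HZ",
    "GRF_CUTOFF_HZ",
    "FOOT_MARKER_CUTOFF_HZ",
    "COM_CUTOFF_HZ",
]

# Filter configuration. The CoP chain uses a 6 Hz fourth-order zero-lag
# Butterworth; vertical GRF a 60 Hz second-order one. Marker cutoffs are a
# per-metric choice within the 8-25 Hz range: 10 Hz for foot markers feeding
# step geometry, 25 Hz for the centre-of-mass / C7 chain.
COP_CUTOFF_HZ = 6.0
GRF_CUTOFF_HZ = 60.0
FOOT_MARKER_CUTOFF_HZ = 10.0
COM_CUTOFF_HZ = 25.0

PELVIS_MARKERS = ("LASI", "RASI", "LPSI", "RPSI")
FOOT_MARKERS = (
    "L_calcaneus", "R_calcaneus",
    "L_metatarsal5", "R_metatarsal5",
    "L_ankle", "R_ankle",
)


@dataclass
class TrialTimeSeries:
    """Synchronised marker and force-plate channels for one walking trial.

    ``markers`` maps a marker name to an ``(n, 3)`` position array in metres
    at ``marker_rate``.  ``forces`` maps a channel name (``fz_left``,
    ``fz_right``, ``cop_x``, ``cop_y``, ``pert_fx``, ``pert_fy``) to a 1-D
    array at ``force_rate``; vertical GRFs in newtons, CoP positions in
    metres.
    """

    marker_time: np.ndarray
    markers: dict[str, np.ndarray]
    force_time: np.ndarray
    forces: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, t in (("marker_time", self.marker_time), ("force_time", self.force_time)):
            t = np.asarray(t, dtype=float)
            if t.ndim != 1 or len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be 1-D and strictly increasing")
        for name, arr in self.markers.items():
            if arr.shape != (len(self.marker_time), 3):
                raise ValueError(f"marker {name!r} has shape {arr.shape}, "
                                 f"expected ({len(self.marker_time)}, 3)")
        for name, arr in self.forces.items():
            if arr.shape != (len(self.force_time),):
                raise ValueError(f"force channel {name!r} has shape {arr.shape}")

    @property
    def marker_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.marker_time)))

    @property
    def force_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.force_time)))

    def pelvis_markers(self) -> dict[str, np.ndarray]:
        sel = {k: v for k, v in self.markers.items() if k in PELVIS_MARKERS}
        if not sel:  # accept any marker whose name suggests a pelvis landmark
            sel = {k: v for k, v in self.markers.items()
                   if "ASI" in k or "PSI" in k or "pelvis" in k.lower()}
        return sel


@dataclass
class ComState:
    """Centre-of-mass position and velocity at the marker rate."""

    position: np.ndarray  # (n, 3) m
    velocity: np.ndarray  # (n, 3) m/s
    time: np.ndarray      # (n,) s
    markers_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position.shape != self.velocity.shape:
            raise ValueError("position and velocity must have the same shape")
        if len(self.time) != len(self.position):
            raise ValueError("time and position must have the same length")


def zero_lag_butterworth(x: np.ndarray, order: int, cutoff: float, rate: float) -> np.ndarray:
    """Forward-backward (zero phase) Butterworth low-pass filter.

    ``order`` is the order of the underlying design; applying it in both
    directions squares the magnitude response, so the gain at ``cutoff`` is
    0.5 rather than the single-pass 1/sqrt(2).  DC gain is exactly 1.

    Filters along the first axis, so ``(n, 3)`` marker arrays work directly.
    """
    x = np.asarray(x, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0.0 < cutoff < rate / 2.0:
        raise ValueError(f"cutoff must lie in (0, Nyquist); got {cutoff} Hz at rate {rate} Hz")
    sos = sp_signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    n_min = 3 * (2 * order + 1)
    if x.shape[0] <= n_min:
        raise ValueError(f"signal too short for edge handling (need > {n_min} samples)")
    return sp_signal.sosfiltfilt(sos, x, axis=0)


def _finite_difference(x: np.ndarray, rate: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the edges."""
    return np.gradient(x, 1.0 / rate, axis=0)


def estimate_com(pelvis_markers: dict[str, np.ndarray], rate: float, *,
                 time: np.ndarray | None = None,
                 cutoff: float = COM_CUTOFF_HZ) -> ComState:
    """Centre of mass as the centroid of the pelvis marker set.

    Position is the per-frame arithmetic mean of the supplied markers;
    velocity is its finite difference, and both are then low-pass filtered
    with a 25 Hz fourth-order zero-lag Butterworth.
    """
    if not pelvis_markers:
        raise ValueError("estimate_com requires at least one pelvis marker channel")
    names = tuple(sorted(pelvis_markers))
    stack = np.stack([np.asarray(pelvis_markers[n], dtype=float) for n in names])
    if np.isnan(stack).any():
        raise ValueError("pelvis markers contain gaps (NaN); gap-filling is out of scope")
    centroid = stack.mean(axis=0)
    velocity = _finite_difference(centroid, rate)
    position = zero_lag_butterworth(centroid, 4, cutoff, rate)
    velocity = zero_lag_butterworth(velocity, 4, cutoff, rate)
    if time is None:
        time = np.arange(len(centroid)) / rate
    return ComState(position=position, velocity=velocity, time=np.asarray(time, float),
                    markers_used=names)


def interp_at(time: np.ndarray, values: np.ndarray, at: np.ndarray | float) -> np.ndarray:
    """Linear interpolation of a channel (1-D or ``(n, k)``) at given times."""
    at = np.atleast_1d(np.asarray(at, dtype=float))
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        return np.interp(at, time, values)
    return np.column_stack([np.interp(at, time, values[:, j]) for j in range(values.shape[1])])


# ---------------------------------------------------------------------------
# Delimited-table dialect
#
# A trial is stored as three text files sharing a base name:
#   <base>_markers.tsv  time_s + <marker>_x/_y/_z columns (SI units, NaN = gap)
#   <base>_forces.tsv   time_s + force/CoP channels
#   <base>_meta.yaml    subject id, condition, trial kind, treadmill speed, ...
# C3D input is accepted only if the optional ezc3d package is installed.
# ---------------------------------------------------------------------------

def write_trial(trial: TrialTimeSeries, directory: str | Path, base: str) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    marker_cols = {"time_s": trial.marker_time}
    for name, arr in trial.markers.items():
        for j, ax in enumerate("xyz"):
            marker_cols[f"{name}_{ax}"] = arr[:, j]
    force_cols = {"time_s": trial.force_time, **trial.forces}
    paths = {
        "markers": directory / f"{base}_markers.tsv",
        "forces": directory / f"{base}_forces.tsv",
        "meta": directory / f"{base}_meta.yaml",
    }
    # %.17g guarantees bit-exact float round-trips through the text tables
    pd.DataFrame(marker_cols).to_csv(paths["markers"], sep="\t", index=False,
                                     float_format="%.17g")
    pd.DataFrame(force_cols).to_csv(paths["forces"], sep="\t", index=False,
                                    float_format="%.17g")
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(trial.meta, fh, sort_keys=True)
    return paths


def read_trial(directory: str | Path, base: str) -> TrialTimeSeries:
    directory = Path(directory)
    if (directory / f"{base}.c3d").exists():
        return _read_c3d(directory / f"{base}.c3d")
    mk = pd.read_csv(directory / f"{base}_markers.tsv", sep="\t",
                     float_precision="round_trip")
    fr = pd.read_csv(directory / f"{base}_forces.tsv", sep="\t",
                     float_precision="round_trip")
    meta_path = directory / f"{base}_meta.yaml"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    markers: dict[str, np.ndarray] = {}
    names = sorted({c[:-2] for c in mk.columns if c.endswith(("_x", "_y", "_z"))})
    for name in names:
        markers[name] = np.column_stack([mk[f"{name}_{ax}"].to_numpy() for ax in "xyz"])
    forces = {c: fr[c].to_numpy() for c in fr.columns if c != "time_s"}
    return TrialTimeSeries(marker_time=mk["time_s"].to_numpy(), markers=markers,
                           force_time=fr["time_s"].to_numpy(), forces=forces, meta=meta)


def _read_c3d(path: Path) -> TrialTimeSeries:  # pragma: no cover - optional dependency
    try:
        import ezc3d
    except ImportError as exc:
        raise ImportError(
            "reading .c3d requires the optional ezc3d package; "
            "use the delimited-table dialect instead") from exc
    c3d = ezc3d.c3d(str(path))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    points = c3d["data"]["points"]  # (4, n_markers, n_frames), mm
    n = points.shape[2]
    time = np.arange(n) / rate
    markers = {lab: points[:3, i, :].T / 1000.0 for i, lab in enumerate(labels)}
    return TrialTimeSeries(marker_time=time, markers=markers,
                           force_time=time, forces={}, meta={"source": str(path)})


def write_perturbation_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["onset_s", "direction", "magnitude_pct_bw", "duration_s"]
    log[cols].to_csv(path, sep="\t", index=False)
    return path


def read_perturbation_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
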