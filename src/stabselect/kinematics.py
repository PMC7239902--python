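"""Kinematic feature extraction from pointing-movement trajectories.

Each trial is a 120 Hz stream of 3-D finger positions for one point-to-point
movement of ~0.15 m.  Positions are zero-phase low-pass filtered (4th-order
Butterworth, 10 Hz cutoff by default — standard for reaching movements),
derivatives are taken by central differences, and 20 base measures covering
velocity, acceleration, jerk, amplitude and path geometry are computed per
movement.  Per participant and condition, the mean and SD of each measure
over retained trials give 40 features per condition and 120 per block.

Conventions: the longitudinal axis is the start-to-end chord; "vertical"
is the z axis (perpendicular to the table plane), measured relative to the
chord baseline; deceleration is the most negative longitudinal acceleration,
reported as a magnitude; timing measures are percentages of the movement
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .matrix import (CONDITIONS, KINEMATIC_MEASURES, FeatureMatrix,
                     feature_id, meta_for_ids)
from .preprocessing import remove_trial_outliers

SAMPLING_HZ = 120.0
DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_FILTER_ORDER = 4
MIN_SAMPLES = 8


@dataclass(frozen=True)
class MovementTrial:
    """One pointing movement: timestamped 3-D positions plus design tags."""

    participant: str
    group: str
    block: str
    condition: str
    trial_index: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        n = self.t.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise ValueError("t, x, y, z must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


def filter_trajectory(trial: MovementTrial,
                      cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                      order: int = DEFAULT_FILTER_ORDER) -> MovementTrial:
    """Zero-phase Butterworth low-pass of the positions; timestamps untouched.

    Forward-backward filtering doubles the effective order and squares the
    single-pass gain, so the passband stays phase-true.
    """
    nyquist = SAMPLING_HZ / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff_hz}")
    if trial.t.size < MIN_SAMPLES:
        raise ValueError(f"trial too short to filter ({trial.t.size} samples)")
    b, a = butter(order, cutoff_hz / nyquist)
    padlen = min(3 * (max(len(a), len(b)) - 1), trial.t.size - 1)
    filtered = filtfilt(b, a, trial.positions, axis=0, padlen=padlen)
    return replace(trial, x=filtered[:, 0], y=filtered[:, 1], z=filtered[:, 2])


def _chord_baseline(values: np.ndarray) -> np.ndarray:
    """Linear interpolation between the first and last value."""
    n = values.size
    return values[0] + (values[-1] - values[0]) * np.linspace(0.0, 1.0, n)


def compute_measures(trial: MovementTrial) -> dict:
    """The 20 base kinematic measures of one (filtered) movement."""
    t = trial.t
    if t.size < 5:
        raise ValueError(f"degenerate trial: {t.size} samples")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("degenerate trial: zero duration")

    pos = trial.positions
    chord = pos[-1] - pos[0]
    chord_len = float(np.linalg.norm(chord))
    if chord_len == 0:
        raise ValueError("degenerate trial: coincident endpoints")
    axis = chord / chord_len

    vel = np.gradient(pos, t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    acc = np.gradient(vel, t, axis=0)
    jerk = np.gradient(acc, t, axis=0)
    jerk_mag = np.linalg.norm(jerk, axis=1)

    longitudinal = (pos - pos[0]) @ axis
    v_long = np.gradient(longitudinal, t)
    a_long = np.gradient(v_long, t)

    pct = lambda i: 100.0 * float(t[i] - t[0]) / duration

    i_pv = int(np.argmax(speed))
    i_pa = int(np.argmax(a_long))
    i_pd = int(np.argmin(a_long))
    i_pj = int(np.argmax(jerk_mag))

    seg = np.diff(pos, axis=0)
    path_length = float(np.linalg.norm(seg, axis=1).sum())

    z_dev = trial.z - _chord_baseline(trial.z)
    i_ph = int(np.argmax(z_dev))
    vertical_amplitude = max(float(z_dev[i_ph]), 0.0)

    # lateral deviation: horizontal distance from the chord's ground-plane track
    xy = pos[:, :2] - pos[0, :2]
    chord_xy = chord[:2]
    norm_xy = np.linalg.norm(chord_xy)
    if norm_xy > 0:
        u = chord_xy / norm_xy
        lateral = xy[:, 0] * (-u[1]) + xy[:, 1] * u[0]
    else:
        lateral = np.linalg.norm(xy, axis=1)
    horizontal_amplitude = float(np.max(np.abs(lateral)))

    peak_speed = float(speed[i_pv])
    peaks, _ = find_peaks(speed, prominence=0.05 * peak_speed)
    n_velocity_peaks = int(max(len(peaks), 1))

    msj = float(np.trapezoid(jerk_mag ** 2, t))
    normalized_jerk = float(np.sqrt(0.5 * msj * duration ** 5 / chord_len ** 2))

    return {
        "duration": duration,
        "peak_velocity": peak_speed,
        "mean_velocity": float(np.trapezoid(speed, t) / duration),
        "pct_to_peak_velocity": pct(i_pv),
        "peak_acceleration": float(a_long[i_pa]),
        "pct_to_peak_acceleration": pct(i_pa),
        "peak_deceleration": float(abs(a_long[i_pd])),
        "pct_to_peak_deceleration": pct(i_pd),
        "mean_abs_acceleration": float(np.abs(a_long).mean()),
        "peak_jerk": float(jerk_mag[i_pj]),
        "pct_to_peak_jerk": pct(i_pj),
        "mean_squared_jerk": float((jerk_mag ** 2).mean()),
        "normalized_jerk": normalized_jerk,
        "vertical_amplitude": vertical_amplitude,
        "pct_to_peak_height": pct(i_ph),
        "horizontal_amplitude": horizontal_amplitude,
        "path_length": path_length,
        "straightness_ratio": max(path_length / chord_len, 1.0),
        "n_velocity_peaks": float(n_velocity_peaks),
        "deceleration_fraction": float(t[-1] - t[i_pv]) / duration,
    }


def measures_table(trials, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_FILTER_ORDER) -> pd.DataFrame:
    """Filter every trial and tabulate its measures (one row per trial)."""
    rows = []
    for trial in trials:
        filtered = filter_trajectory(trial, cutoff_hz=cutoff_hz, order=order)
        row = {
            "participant": trial.participant,
            "group": trial.group,
            "block": trial.block,
            "condition": trial.condition,
            "trial_index": trial.trial_index,
        }
        row.update(compute_measures(filtered))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_features(measures: pd.DataFrame, block: str,
                       trial_outlier_removal: bool = False) -> FeatureMatrix:
    """Participant x feature matrix for one block: mean and SD per measure.

    ``measures`` is the per-trial table from :func:`measures_table`.  With
    ``trial_outlier_removal`` the non-recursive criterion is applied per
    participant, condition and measure before aggregating.  Cells backed by
    fewer than two retained trials are left missing for downstream
    imputation.
    """
    sub = measures[measures["block"] == block]
    unknown = set(sub["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition tag(s): {sorted(unknown)}")

    participants = sorted(sub["participant"].unique())
    groups = sub.groupby("participant")["group"].first()

    fids = [feature_id("kinematic", block, cond, meas, stat)
            for cond in CONDITIONS for meas in KINEMATIC_MEASURES
            for stat in ("mean", "sd")]
    values = pd.DataFrame(np.nan, index=participants, columns=fids)

    for (pid, cond), chunk in sub.groupby(["participant", "condition"]):
        for meas in KINEMATIC_MEASURES:
            vals = chunk[meas].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if trial_outlier_removal:
                vals = remove_trial_outliers(vals)
            if vals.size < 2:
                continue
            values.loc[pid, feature_id("kinematic", block, cond, meas, "mean")] = vals.mean()
            values.loc[pid, feature_id("kinematic", block, cond, meas, "sd")] = vals.std(ddof=1)

    labels = groups.reindex(participants)
    labels.index.name = None
    values.index.name = None
    return FeatureMatrix(values, labels, meta_for_ids(fids))
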