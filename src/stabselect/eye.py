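"""Eye-movement feature extraction from pre-parsed gaze events.

Saccade and fixation events arrive already detected (as produced by vendor
event parsers); this module reduces them to 8 per-trial measures — saccade
count, amplitude, duration and peak velocity, first-saccade latency,
fixation duration, percentage of fixation time dwelling on the moving
finger, and mean gaze-to-finger angular distance — and aggregates the mean
and SD of each over retained trials per participant and condition:
8 x 2 x 3 conditions = 48 features per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import (CONDITIONS, EYE_MEASURES, FeatureMatrix, feature_id,
                     meta_for_ids)
from .preprocessing import remove_trial_outliers, screen_missing_gaze


@dataclass(frozen=True)
class Saccade:
    onset: float        # s from trial start
    amplitude: float    # deg
    duration: float     # ms
    peak_velocity: float  # deg/s


@dataclass(frozen=True)
class Fixation:
    onset: float      # s from trial start
    duration: float   # ms
    on_finger: bool


@dataclass(frozen=True)
class GazeTrial:
    """Pre-parsed eye events for one trial plus trial-level summaries."""

    participant: str
    group: str
    block: str
    condition: str
    trial_index: int
    saccades: tuple[Saccade, ...] = ()
    fixations: tuple[Fixation, ...] = ()
    missing_fraction: float = 0.0
    gaze_finger_distance: float = float("nan")  # deg, vendor-style summary

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError(
                f"missing_fraction must lie in [0, 1], got {self.missing_fraction}")


def trial_measures(trial: GazeTrial) -> dict:
    """The 8 base eye measures of one gaze trial (NaN where undefined)."""
    sac = trial.saccades
    fix = trial.fixations
    nan = float("nan")
    if sac:
        amp = np.array([s.amplitude for s in sac], dtype=float)
        dur = np.array([s.duration for s in sac], dtype=float)
        pv = np.array([s.peak_velocity for s in sac], dtype=float)
        onset = np.array([s.onset for s in sac], dtype=float)
        sac_vals = dict(
            saccade_count=float(len(sac)),
            saccade_amplitude=float(amp.mean()),
            saccade_duration=float(dur.mean()),
            saccade_peak_velocity=float(pv.mean()),
            first_saccade_latency=float(onset.min() * 1000.0),
        )
    else:
        sac_vals = dict(saccade_count=0.0, saccade_amplitude=nan,
                        saccade_duration=nan, saccade_peak_velocity=nan,
                        first_saccade_latency=nan)
    if fix:
        fdur = np.array([f.duration for f in fix], dtype=float)
        flag = np.array([f.on_finger for f in fix], dtype=float)
        dwell = 100.0 * float((fdur * flag).sum() / fdur.sum()) if fdur.sum() > 0 else nan
        fix_vals = dict(fixation_duration=float(fdur.mean()),
                        pct_dwell_on_finger=dwell)
    else:
        fix_vals = dict(fixation_duration=nan, pct_dwell_on_finger=nan)
    return {**sac_vals, **fix_vals,
            "gaze_finger_distance": float(trial.gaze_finger_distance)}


def eye_measures_table(trials, screen: bool = True) -> pd.DataFrame:
    """Per-trial eye measure table; optionally pre-screen missing-data trials."""
    if screen:
        trials = screen_missing_gaze(trials)
    rows = []
    for trial in trials:
        row = {
            "participant": trial.participant,
            "group": trial.group,
            "block": trial.block,
            "condition": trial.condition,
            "trial_index": trial.trial_index,
        }
        row.update(trial_measures(trial))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_eye_features(gaze_trials, block: str,
                           screen: bool = True,
                           trial_outlier_removal: bool = False,
                           participants=None) -> FeatureMatrix:
    """Participant x feature matrix for one block (48 eye columns).

    Participants whose trials were all screened out get an all-missing row
    (imputation happens downstream).  Pass ``participants`` as an ordered
    {participant: group} mapping to pin the row set; otherwise rows are the
    participants present in the unscreened trial list.
    """
    if participants is None:
        participants = {}
        for trial in gaze_trials:
            participants.setdefault(trial.participant, trial.group)

    table = eye_measures_table(gaze_trials, screen=screen)
    if not table.empty:
        table = table[table["block"] == block]
        unknown = set(table["condition"]) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition tag(s): {sorted(unknown)}")

    fids = [feature_id("eye", block, cond, meas, stat)
            for cond in CONDITIONS for meas in EYE_MEASURES
            for stat in ("mean", "sd")]
    index = list(participants)
    values = pd.DataFrame(np.nan, index=index, columns=fids)

    if not table.empty:
        for (pid, cond), chunk in table.groupby(["participant", "condition"]):
            for meas in EYE_MEASURES:
                vals = chunk[meas].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if trial_outlier_removal:
                    vals = remove_trial_outliers(vals)
                if vals.size < 2:
                    continue
                values.loc[pid, feature_id("eye", block, cond, meas, "mean")] = vals.mean()
                values.loc[pid, feature_id("eye", block, cond, meas, "sd")] = vals.std(ddof=1)

    labels = pd.Series({pid: grp for pid, grp in participants.items()})
    labels = labels.reindex(index)
    return FeatureMatrix(values, labels, meta_for_ids(fids))
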