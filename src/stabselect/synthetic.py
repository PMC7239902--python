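"""Synthetic cohort generator with planted group effects.

Two routes produce data with the statistical structure the analysis assumes:

``generate_feature_matrix``
    Samples participant-level feature matrices directly from a correlated
    Gaussian model.  Each modality shares a single latent factor whose
    loading is chosen so that the pairwise feature correlation equals the
    target mean correlation (0.20 for kinematic, 0.48 for eye features).
    Features are standardised (unit variance), so a planted effect size d
    is simply a group mean shift of d.  SD-statistic features additionally
    carry a small positive shift for the autistic group derived from the
    trial-level variability inflation, emulating broadly elevated movement
    variability.

``generate_trials``
    Synthesises trial-level recordings: smooth minimum-jerk pointing
    trajectories (0.15 m, 120 Hz) with a condition-dependent vertical
    component, and pre-parsed gaze events.  Group effects are injected on
    the generative parameters (height, duration, timing skew, ...) so that
    features extracted downstream carry approximately the planted effect
    sizes; the calibration shifts each parameter by d times the
    between-participant SD of the corresponding extracted feature.

Both routes draw the development and test samples from one population
(identical planted structure, independent seeded draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eye import Fixation, GazeTrial, Saccade
from .kinematics import MovementTrial, SAMPLING_HZ
from .matrix import (BLOCKS, CONDITIONS, EYE_MEASURES, FeatureMatrix,
                     GROUP_AUTISTIC, GROUP_CONTROL, KINEMATIC_MEASURES,
                     feature_id, feature_universe, meta_for_ids,
                     parse_feature_id)

# --------------------------------------------------------------------------
# study conditions

#: Default planted group effects: ten features, mostly elevated-condition
#: amplitude/acceleration measures, with standardized effect sizes in the
#: 0.75-0.93 range (autistic group lower on means, higher on SDs).
DEFAULT_PLANTED: tuple[tuple[str, float], ...] = (
    (feature_id("kinematic", "general", "elevated", "vertical_amplitude", "mean"), 0.93),
    (feature_id("kinematic", "general", "elevated", "pct_to_peak_acceleration", "mean"), 0.75),
    (feature_id("kinematic", "general", "elevated", "pct_to_peak_deceleration", "mean"), 0.90),
    (feature_id("kinematic", "general", "elevated", "pct_to_peak_height", "mean"), 0.78),
    (feature_id("kinematic", "general", "elevated", "peak_acceleration", "mean"), 0.80),
    (feature_id("kinematic", "general", "elevated", "vertical_amplitude", "sd"), 0.75),
    (feature_id("kinematic", "general", "elevated", "horizontal_amplitude", "mean"), 0.77),
    (feature_id("kinematic", "general", "direct", "peak_velocity", "mean"), 0.76),
    (feature_id("kinematic", "general", "direct", "vertical_amplitude", "mean"), 0.75),
    (feature_id("kinematic", "general", "direct-fast", "duration", "mean"), 0.80),
)

#: Movement length between the two pointing locations (m).
MOVEMENT_LENGTH = 0.15

#: Per-condition trajectory baselines: movement time (s) and apex height (m).
MOVEMENT_BASE = {
    "direct": {"duration": 0.45, "height": 0.02},
    "elevated": {"duration": 0.55, "height": 0.08},
    "direct-fast": {"duration": 0.30, "height": 0.02},
}
_MOVEMENT_COMMON = {"apex": 0.5, "skew": 1.0, "lateral": 0.005}
MOVEMENT_PARAMS = ("duration", "height", "apex", "skew", "lateral")

#: Between-participant and trial-to-trial SDs of the trajectory parameters.
MOVEMENT_SIGMA_P = {"duration": 0.05, "height": 0.012, "apex": 0.04,
                    "skew": 0.08, "lateral": 0.002}
MOVEMENT_SIGMA_T = {"duration": 0.04, "height": 0.008, "apex": 0.03,
                    "skew": 0.06, "lateral": 0.0015}

_PARAM_BOUNDS = {"duration": (0.15, 1.2), "height": (0.001, 0.2),
                 "apex": (0.2, 0.8), "skew": (0.5, 1.8),
                 "lateral": (0.0, 0.05)}

#: Which generative parameter drives each kinematic measure when planting
#: trial-level group effects.
PARAM_FOR_MEASURE = {
    "duration": "duration",
    "peak_velocity": "duration",
    "mean_velocity": "duration",
    "peak_acceleration": "duration",
    "peak_deceleration": "duration",
    "mean_abs_acceleration": "duration",
    "peak_jerk": "duration",
    "mean_squared_jerk": "duration",
    "normalized_jerk": "duration",
    "pct_to_peak_velocity": "skew",
    "pct_to_peak_acceleration": "skew",
    "pct_to_peak_deceleration": "skew",
    "pct_to_peak_jerk": "skew",
    "deceleration_fraction": "skew",
    "vertical_amplitude": "height",
    "pct_to_peak_height": "apex",
    "horizontal_amplitude": "lateral",
    "path_length": "lateral",
    "straightness_ratio": "lateral",
}

#: Per-condition video length (s) used for gaze trials.
GAZE_TRIAL_DURATION = {"direct": 2.5, "elevated": 3.0, "direct-fast": 2.0}

#: Eye measure baselines with between-participant and trial SDs.
EYE_BASE = {
    "saccade_count": (4.0, 0.8, 1.0),
    "saccade_amplitude": (4.0, 0.6, 0.8),          # deg
    "saccade_duration": (45.0, 4.0, 5.0),          # ms
    "saccade_peak_velocity": (180.0, 20.0, 25.0),  # deg/s
    "first_saccade_latency": (250.0, 30.0, 40.0),  # ms
    "fixation_duration": (350.0, 40.0, 50.0),      # ms
    "pct_dwell_on_finger": (55.0, 8.0, 10.0),      # %
    "gaze_finger_distance": (3.0, 0.5, 0.7),       # deg
}

#: Mean shift (in feature SD units) applied to the autistic group on every
#: SD-statistic feature, per unit of variability inflation above 1; at the
#: default inflation 1.3 this gives d = 0.25, i.e. roughly three quarters of
#: variability features higher in the autistic group at n = 15 + 15.
SD_SHIFT_PER_INFLATION = 0.25 / 0.3


@dataclass(frozen=True)
class CohortSpec:
    """Population definition for the synthetic cohort.

    The defaults are the study conditions: 15 + 15 development and 7 + 7
    test participants, a planted 10-feature signal with d in [0.75, 0.93]
    concentrated in elevated-condition amplitude/acceleration features,
    mean inter-feature correlations of 0.20 (kinematic) and 0.48 (eye),
    and 1.3-fold trial-level variability inflation in the autistic group.
    """

    n_per_group_dev: int = 15
    n_per_group_test: int = 7
    trials_per_condition: int = 10
    planted_features: tuple[tuple[str, float], ...] = DEFAULT_PLANTED
    mean_corr_kinematic: float = 0.20
    mean_corr_eye: float = 0.48
    variability_inflation: float = 1.3
    missing_gaze_fraction: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_group_dev", "n_per_group_test", "trials_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("mean_corr_kinematic", "mean_corr_eye"):
            value = getattr(self, name)
            if not 0.0 <= value < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {value}")
        if self.variability_inflation <= 0:
            raise ValueError("variability_inflation must be positive")
        if not 0.0 <= self.missing_gaze_fraction <= 1.0:
            raise ValueError("missing_gaze_fraction must lie in [0, 1]")
        universe = set(feature_universe())
        for fid, d in self.planted_features:
            if fid not in universe:
                raise ValueError(f"effect planted on unknown feature id {fid!r}")
            if not math.isfinite(d):
                raise ValueError(f"effect size for {fid!r} must be finite")

    def planted_ids(self) -> list[str]:
        return [fid for fid, _ in self.planted_features]


def _seed_streams(spec: CohortSpec):
    dev_ss, test_ss, trial_ss = np.random.SeedSequence(spec.seed).spawn(3)
    return dev_ss, test_ss, trial_ss


# --------------------------------------------------------------------------
# direct feature-matrix sampling

def _autistic_shift_vector(spec: CohortSpec, meta: pd.DataFrame) -> np.ndarray:
    """Standardised mean shift applied to autistic rows, per feature."""
    sd_shift = (spec.variability_inflation - 1.0) * SD_SHIFT_PER_INFLATION
    shift = np.where(meta["statistic"].to_numpy() == "sd", sd_shift, 0.0)
    index = {fid: i for i, fid in enumerate(meta.index)}
    for fid, d in spec.planted_features:
        if fid in index:
            sign = 1.0 if parse_feature_id(fid)["statistic"] == "sd" else -1.0
            shift[index[fid]] = sign * d
    return shift


def _sample_ids(prefix: str, n_per_group: int) -> tuple[list[str], pd.Series]:
    ids = [f"{prefix}A{i + 1:02d}" for i in range(n_per_group)]
    ids += [f"{prefix}N{i + 1:02d}" for i in range(n_per_group)]
    labels = pd.Series([GROUP_AUTISTIC] * n_per_group +
                       [GROUP_CONTROL] * n_per_group, index=ids, name="group")
    return ids, labels


def generate_feature_matrix(spec: CohortSpec, blocks=BLOCKS,
                            partition: str = "dev") -> FeatureMatrix:
    """Sample a participant x feature matrix for one partition.

    Parameters
    ----------
    blocks
        Experimental blocks to include; one block gives 168 columns
        (120 kinematic + 48 eye).
    partition
        ``"dev"`` (15 + 15 by default) or ``"test"`` (7 + 7); both are
        independent draws from the same planted population.
    """
    spec.validate()
    if partition not in ("dev", "test"):
        raise ValueError(f"partition must be 'dev' or 'test', got {partition!r}")
    dev_ss, test_ss, _ = _seed_streams(spec)
    rng = np.random.default_rng(dev_ss if partition == "dev" else test_ss)
    n = spec.n_per_group_dev if partition == "dev" else spec.n_per_group_test
    prefix = "dev" if partition == "dev" else "tst"

    fids = feature_universe(blocks)
    meta = meta_for_ids(fids)
    n_total = 2 * n
    X = np.empty((n_total, len(fids)))
    loading = {"kinematic": math.sqrt(spec.mean_corr_kinematic),
               "eye": math.sqrt(spec.mean_corr_eye)}
    modality = meta["modality"].to_numpy()
    block_col = meta["block"].to_numpy()
    for block in blocks:
        for mod, a in loading.items():
            cols = np.flatnonzero((modality == mod) & (block_col == block))
            g = rng.standard_normal((n_total, 1))
            eps = rng.standard_normal((n_total, cols.size))
            X[:, cols] = a * g + math.sqrt(1.0 - a * a) * eps

    X[:n] += _autistic_shift_vector(spec, meta)
    ids, labels = _sample_ids(prefix, n)
    values = pd.DataFrame(X, index=ids, columns=fids)
    return FeatureMatrix(values, labels, meta)


def generate_dev_test(spec: CohortSpec, blocks=BLOCKS):
    """Development and test matrices — one population, two seeded draws."""
    return (generate_feature_matrix(spec, blocks, "dev"),
            generate_feature_matrix(spec, blocks, "test"))


# --------------------------------------------------------------------------
# trial-level generation

def _c4(n: int) -> float:
    """Bias factor of the sample SD under normality: E[s] = c4 * sigma."""
    from scipy.special import gammaln
    return math.sqrt(2.0 / (n - 1)) * math.exp(
        gammaln(n / 2.0) - gammaln((n - 1) / 2.0))


def _feature_scale(sigma_p: float, sigma_t: float, spec: CohortSpec) -> float:
    """Between-participant SD of a trial-mean feature (pooled over groups)."""
    v = spec.variability_inflation
    T = spec.trials_per_condition
    return math.sqrt(sigma_p ** 2 + sigma_t ** 2 * (1.0 + v * v) / 2.0 / T)


def _movement_adjustments(spec: CohortSpec):
    """Group parameter shifts and trial-noise multipliers from planted ids.

    Returns ``(shifts, noise_mult)`` keyed by (block, condition, parameter):
    autistic parameter-mean shifts for mean-statistic plants, and total
    autistic trial-noise multipliers (replacing the generic inflation) for
    SD-statistic plants.
    """
    shifts: dict[tuple, list] = {}
    noise_mult: dict[tuple, float] = {}
    v = spec.variability_inflation
    T = spec.trials_per_condition
    c4 = _c4(T)
    for fid, d in spec.planted_features:
        info = parse_feature_id(fid)
        if info["modality"] != "kinematic":
            continue
        measure = info["measure"]
        param = PARAM_FOR_MEASURE.get(measure)
        if param is None:
            raise ValueError(
                f"planting on {measure!r} is not supported at trial level")
        key = (info["block"], info["condition"], param)
        if info["statistic"] == "mean":
            delta = d * _feature_scale(MOVEMENT_SIGMA_P[param],
                                       MOVEMENT_SIGMA_T[param], spec)
            shifts.setdefault(key, []).append(-delta)
        else:
            pooled = (math.sqrt(1.0 - c4 * c4) *
                      math.sqrt((1.0 + v * v) / 2.0))
            noise_mult[key] = 1.0 + d * pooled / c4
    return ({k: float(np.mean(vs)) for k, vs in shifts.items()}, noise_mult)


def _eye_adjustments(spec: CohortSpec):
    shifts: dict[tuple, float] = {}
    noise_mult: dict[tuple, float] = {}
    v = spec.variability_inflation
    c4 = _c4(spec.trials_per_condition)
    for fid, d in spec.planted_features:
        info = parse_feature_id(fid)
        if info["modality"] != "eye":
            continue
        measure = info["measure"]
        _, sigma_p, sigma_t = EYE_BASE[measure]
        key = (info["block"], info["condition"], measure)
        if info["statistic"] == "mean":
            shifts[key] = -d * _feature_scale(sigma_p, sigma_t, spec)
        else:
            pooled = math.sqrt(1.0 - c4 * c4) * math.sqrt((1.0 + v * v) / 2.0)
            noise_mult[key] = 1.0 + d * pooled / c4
    return shifts, noise_mult


def _participants(spec: CohortSpec):
    out = []
    for prefix, n in (("dev", spec.n_per_group_dev),
                      ("tst", spec.n_per_group_test)):
        ids, labels = _sample_ids(prefix, n)
        out.extend((pid, labels[pid]) for pid in ids)
    return out


def _clip(param: str, value: float) -> float:
    lo, hi = _PARAM_BOUNDS[param]
    return float(min(max(value, lo), hi))


def _movement_samples(params: dict, rng: np.random.Generator) -> MovementTrial | tuple:
    """Sampled 120 Hz trajectory for one trial from its parameter set."""
    duration = params["duration"]
    n = int(round(duration * SAMPLING_HZ)) + 1
    n = max(n, 13)
    t = np.arange(n) / SAMPLING_HZ
    tau = t / t[-1]
    w = tau ** params["skew"]
    x = MOVEMENT_LENGTH * (10 * w ** 3 - 15 * w ** 4 + 6 * w ** 5)
    p = params["apex"]
    c = 4.0
    alpha, beta = 1.0 + c * p, 1.0 + c * (1.0 - p)
    with np.errstate(divide="ignore"):
        bump = tau ** alpha * (1.0 - tau) ** beta
    peak = bump.max()
    z = params["height"] * bump / peak if peak > 0 else np.zeros_like(tau)
    y = params["lateral"] * np.sin(np.pi * tau)
    noise = 3e-4 * rng.standard_normal((n, 3))
    return t, x + noise[:, 0], y + noise[:, 1], z + noise[:, 2]


def generate_trials(spec: CohortSpec):
    """Trial-level movement and gaze recordings for all participants.

    Returns ``(movement_trials, gaze_trials)`` covering development and
    test participants, 3 conditions x 2 blocks x ``trials_per_condition``
    each.  Group effects are injected on the generative parameters so that
    downstream extracted features carry approximately the planted effect
    sizes; autistic trial-to-trial parameter SDs are scaled by the
    variability inflation factor.
    """
    spec.validate()
    _, _, trial_ss = _seed_streams(spec)
    rng = np.random.default_rng(trial_ss)
    move_shift, move_mult = _movement_adjustments(spec)
    eye_shift, eye_mult = _eye_adjustments(spec)
    rk = math.sqrt(spec.mean_corr_kinematic)
    re = math.sqrt(spec.mean_corr_eye)
    v = spec.variability_inflation

    movement_trials: list[MovementTrial] = []
    gaze_trials: list[GazeTrial] = []
    for pid, group in _participants(spec):
        autistic = group == GROUP_AUTISTIC
        noise_scale = v if autistic else 1.0
        gk = rng.standard_normal()
        ge = rng.standard_normal()
        move_latent = {}
        for cond in CONDITIONS:
            for param in MOVEMENT_PARAMS:
                u = rk * gk + math.sqrt(1.0 - rk * rk) * rng.standard_normal()
                base = MOVEMENT_BASE[cond].get(param, _MOVEMENT_COMMON.get(param))
                move_latent[(cond, param)] = base + MOVEMENT_SIGMA_P[param] * u
        eye_latent = {}
        for cond in CONDITIONS:
            for meas in EYE_MEASURES:
                base, sigma_p, _ = EYE_BASE[meas]
                u = re * ge + math.sqrt(1.0 - re * re) * rng.standard_normal()
                eye_latent[(cond, meas)] = base + sigma_p * u

        for block in BLOCKS:
            for cond in CONDITIONS:
                for idx in range(spec.trials_per_condition):
                    params = {}
                    for param in MOVEMENT_PARAMS:
                        value = move_latent[(cond, param)]
                        mult = noise_scale
                        if autistic:
                            value += move_shift.get((block, cond, param), 0.0)
                            mult = move_mult.get((block, cond, param), mult)
                        value += MOVEMENT_SIGMA_T[param] * mult * rng.standard_normal()
                        params[param] = _clip(param, value)
                    t, x, y, z = _movement_samples(params, rng)
                    movement_trials.append(MovementTrial(
                        participant=pid, group=group, block=block,
                        condition=cond, trial_index=idx, t=t, x=x, y=y, z=z))
                    gaze_trials.append(_gaze_trial(
                        spec, pid, group, block, cond, idx, eye_latent,
                        eye_shift, eye_mult, noise_scale, rng))
    return movement_trials, gaze_trials


def _gaze_trial(spec, pid, group, block, cond, idx, latent, shifts, mults,
                noise_scale, rng) -> GazeTrial:
    autistic = group == GROUP_AUTISTIC
    target = {}
    for meas in EYE_MEASURES:
        base, _, sigma_t = EYE_BASE[meas]
        value = latent[(cond, meas)]
        mult = noise_scale
        if autistic:
            value += shifts.get((block, cond, meas), 0.0)
            mult = mults.get((block, cond, meas), mult)
        target[meas] = value + sigma_t * mult * rng.standard_normal()

    duration = GAZE_TRIAL_DURATION[cond]
    n_sac = max(1, int(round(target["saccade_count"])))
    first = min(max(target["first_saccade_latency"] / 1000.0, 0.05),
                duration - 0.2)
    onsets = np.sort(np.concatenate(
        [[first], rng.uniform(first, duration - 0.05, size=n_sac - 1)]))
    amp = np.maximum(rng.normal(target["saccade_amplitude"],
                                0.15 * abs(target["saccade_amplitude"]) + 0.1,
                                size=n_sac), 0.2)
    dur = np.maximum(rng.normal(target["saccade_duration"], 4.0, size=n_sac), 10.0)
    pv = np.maximum(rng.normal(target["saccade_peak_velocity"], 15.0, size=n_sac), 30.0)
    saccades = tuple(Saccade(float(o), float(a), float(d), float(p))
                     for o, a, d, p in zip(onsets, amp, dur, pv))

    n_fix = n_sac + 1
    fdur = np.maximum(rng.normal(target["fixation_duration"], 25.0, size=n_fix), 40.0)
    fonsets = np.sort(rng.uniform(0.0, duration - 0.05, size=n_fix))
    dwell_p = min(max(target["pct_dwell_on_finger"] / 100.0, 0.0), 1.0)
    flags = rng.random(n_fix) < dwell_p
    fixations = tuple(Fixation(float(o), float(d), bool(f))
                      for o, d, f in zip(fonsets, fdur, flags))

    missing = 0.0
    if rng.random() < spec.missing_gaze_fraction:
        missing = float(rng.uniform(0.0, 0.6))
    return GazeTrial(participant=pid, group=group, block=block, condition=cond,
                     trial_index=idx, saccades=saccades, fixations=fixations,
                     missing_fraction=missing,
                     gaze_finger_distance=max(float(target["gaze_finger_distance"]), 0.1))


# --------------------------------------------------------------------------
# TSV dialects

def write_trials_tsv(trials, path) -> None:
    """Long-format TSV: one position sample per row."""
    frames = []
    for trial in trials:
        frames.append(pd.DataFrame({
            "participant": trial.participant, "group": trial.group,
            "block": trial.block, "condition": trial.condition,
            "trial": trial.trial_index, "t": trial.t,
            "x": trial.x, "y": trial.y, "z": trial.z,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> list[MovementTrial]:
    df = pd.read_csv(path, sep="\t")
    required = {"participant", "group", "block", "condition", "trial",
                "t", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial TSV columns {sorted(missing)}")
    trials = []
    keys = ["participant", "group", "block", "condition", "trial"]
    for (pid, group, block, cond, idx), chunk in df.groupby(keys, sort=False):
        chunk = chunk.sort_values("t")
        trials.append(MovementTrial(
            participant=str(pid), group=str(group), block=str(block),
            condition=str(cond), trial_index=int(idx),
            t=chunk["t"].to_numpy(float), x=chunk["x"].to_numpy(float),
            y=chunk["y"].to_numpy(float), z=chunk["z"].to_numpy(float)))
    return trials


_GAZE_COLUMNS = ["participant", "group", "block", "condition", "trial",
                 "event", "onset", "duration", "amplitude", "peak_velocity",
                 "on_finger", "missing_fraction", "gaze_finger_distance"]


def write_gaze_tsv(trials, path) -> None:
    """Event-level TSV: one saccade/fixation per row plus a summary row."""
    rows = []
    for trial in trials:
        head = [trial.participant, trial.group, trial.block, trial.condition,
                trial.trial_index]
        tail = [trial.missing_fraction, trial.gaze_finger_distance]
        rows.append(head + ["trial", np.nan, np.nan, np.nan, np.nan, np.nan] + tail)
        for s in trial.saccades:
            rows.append(head + ["saccade", s.onset, s.duration, s.amplitude,
                                s.peak_velocity, np.nan] + tail)
        for f in trial.fixations:
            rows.append(head + ["fixation", f.onset, f.duration, np.nan,
                                np.nan, int(f.on_finger)] + tail)
    pd.DataFrame(rows, columns=_GAZE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path) -> list[GazeTrial]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing gaze TSV columns {sorted(missing)}")
    trials = []
    keys = ["participant", "group", "block", "condition", "trial"]
    for (pid, group, block, cond, idx), chunk in df.groupby(keys, sort=False):
        sacs = tuple(
            Saccade(float(r.onset), float(r.amplitude), float(r.duration),
                    float(r.peak_velocity))
            for r in chunk[chunk["event"] == "saccade"].itertuples())
        fixs = tuple(
            Fixation(float(r.onset), float(r.duration), bool(int(r.on_finger)))
            for r in chunk[chunk["event"] == "fixation"].itertuples())
        trials.append(GazeTrial(
            participant=str(pid), group=str(group), block=str(block),
            condition=str(cond), trial_index=int(idx), saccades=sacs,
            fixations=fixs,
            missing_fraction=float(chunk["missing_fraction"].iloc[0]),
            gaze_finger_distance=float(chunk["gaze_finger_distance"].iloc[0])))
    return trials
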