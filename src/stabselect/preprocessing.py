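"""Outlier handling, missing-data screening, imputation and z-scoring.

Trial-level outliers use the non-recursive sample-size-dependent criterion of
Van Selst & Jolicoeur (1994): an observation is removed when it lies more
than C(n) sample SDs from the sample mean, where C(n) grows from 1.458 at
n = 4 towards the asymptote 2.50 at n >= 100 (linear interpolation between
tabulated sample sizes).  The criterion is evaluated once on the full sample
— no recursion — which keeps the expected exclusion rate roughly constant
across sample sizes.

Normalisation is a plain z-score whose parameters (per-feature mean and
unbiased SD) are always estimated on training rows only; constant training
features fall back to divisor 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix, GROUPS

#: Non-recursive criterion C(n), tabulated by sample size.
VAN_SELST_JOLICOEUR_TABLE: tuple[tuple[int, float], ...] = (
    (4, 1.458), (5, 1.68), (6, 1.841), (7, 1.961), (8, 2.050),
    (9, 2.12), (10, 2.173), (11, 2.22), (12, 2.246), (13, 2.274),
    (14, 2.31), (15, 2.326), (16, 2.339), (17, 2.35), (18, 2.361),
    (19, 2.365), (20, 2.391), (25, 2.41), (30, 2.4305), (35, 2.45),
    (50, 2.48), (100, 2.50),
)

_VSJ_N = np.array([n for n, _ in VAN_SELST_JOLICOEUR_TABLE], dtype=float)
_VSJ_C = np.array([c for _, c in VAN_SELST_JOLICOEUR_TABLE], dtype=float)

#: Below this sample size no removal is attempted.
MIN_N_FOR_REMOVAL = 4

#: Gaze trials with more than this fraction of missing samples are dropped.
MISSING_GAZE_LIMIT = 1.0 / 3.0


def outlier_criterion(n: int) -> float:
    """SD-multiple criterion C(n); constant 2.50 for n >= 100."""
    if n < MIN_N_FOR_REMOVAL:
        return float("inf")
    return float(np.interp(n, _VSJ_N, _VSJ_C))


def outlier_mask(values: np.ndarray) -> np.ndarray:
    """Boolean mask of observations flagged by the C(n)*SD criterion.

    NaNs are never flagged (they are handled by imputation, not removal).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n = int(finite.sum())
    mask = np.zeros(values.shape, dtype=bool)
    if n < MIN_N_FOR_REMOVAL:
        return mask
    mean = values[finite].mean()
    sd = values[finite].std(ddof=1)
    if sd == 0:
        return mask
    crit = outlier_criterion(n)
    mask[finite] = np.abs(values[finite] - mean) > crit * sd
    return mask


def remove_trial_outliers(values) -> np.ndarray:
    """Retained observations after one pass of the non-recursive criterion.

    Inputs with fewer than four finite observations pass through unchanged.
    """
    values = np.asarray(values, dtype=float)
    return values[~outlier_mask(values)]


def screen_missing_gaze(trials):
    """Drop gaze trials whose missing-data fraction exceeds 1/3 (strict)."""
    retained = []
    for trial in trials:
        frac = getattr(trial, "missing_fraction", None)
        if frac is None or not np.isfinite(frac):
            raise ValueError(f"gaze trial {trial!r} has no missing_fraction")
        if frac <= MISSING_GAZE_LIMIT:
            retained.append(trial)
    return retained


def impute_group_outliers_and_missing(matrix: FeatureMatrix,
                                      reference: FeatureMatrix | None = None,
                                      strict: bool = False) -> FeatureMatrix:
    """Replace group-level outliers and missing cells with group means.

    Per feature and per group, participants flagged by the same C(n)*SD
    criterion are replaced by the mean of the unflagged group members; any
    remaining missing values are replaced by the group mean.  When
    ``reference`` is given (a development-set matrix), replacement means are
    taken from it so that a held-out set never informs its own imputation.
    With ``strict=True`` labels are ignored entirely and pooled means are
    used — a sensitivity mode for auditing label-aware imputation.
    """
    out = matrix.copy()
    values = out.values

    def _fill_values(col: pd.Series, ref_col: pd.Series) -> pd.Series:
        mask = outlier_mask(col.to_numpy())
        ref_mask = outlier_mask(ref_col.to_numpy())
        clean = ref_col.to_numpy(dtype=float)[~ref_mask]
        clean = clean[np.isfinite(clean)]
        if clean.size == 0:
            raise ValueError(
                f"feature {col.name!r} has no usable values to impute from")
        fill = clean.mean()
        col = col.copy()
        col[mask] = fill
        col[col.isna()] = fill
        return col

    ref = reference.values if reference is not None else values
    ref_labels = reference.labels if reference is not None else out.labels
    for fid in out.feature_ids:
        if strict:
            values[fid] = _fill_values(values[fid], ref[fid])
            continue
        for group in GROUPS:
            rows = out.labels == group
            if not rows.any():
                continue
            ref_rows = ref_labels == group
            if not ref_rows.any():
                raise ValueError(f"reference matrix has no {group!r} samples")
            filled = _fill_values(values.loc[rows, fid], ref.loc[ref_rows, fid])
            values.loc[rows, fid] = filled
    return out


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature z-score parameters estimated on a training set."""

    feature_ids: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray  # zero-SD features recorded with fallback divisor 1

    def __post_init__(self):
        if not (len(self.feature_ids) == self.mean.size == self.sd.size):
            raise ValueError("parameter count must equal feature count")


def fit_zscore(train, feature_ids=None) -> NormalizationParams:
    """Estimate per-feature mean and unbiased SD on training rows only."""
    if isinstance(train, FeatureMatrix):
        ids = tuple(train.feature_ids)
        X = train.values.to_numpy(dtype=float)
    else:
        X = np.asarray(train, dtype=float)
        ids = (tuple(feature_ids) if feature_ids is not None
               else tuple(str(i) for i in range(X.shape[1])))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return NormalizationParams(ids, mean, sd)


def apply_zscore(params: NormalizationParams, matrix):
    """(x - mean) / SD with training-derived parameters."""
    if isinstance(matrix, FeatureMatrix):
        if tuple(matrix.feature_ids) != params.feature_ids:
            raise ValueError("feature ids do not match the fitted parameters")
        values = (matrix.values - params.mean) / params.sd
        return FeatureMatrix(values, matrix.labels, matrix.feature_meta)
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != params.mean.size:
        raise ValueError("feature count does not match the fitted parameters")
    return (X - params.mean) / params.sd
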