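"""Feature-matrix container and the CSV dialect shared across the pipeline.

A :class:`FeatureMatrix` is the central in-memory object: a samples x features
table of real values, a two-class group label per sample, and five pieces of
metadata per feature column (modality, block, condition, base measure,
statistic).  The canonical feature universe has, per experimental block,
120 kinematic columns (3 conditions x 20 measures x {mean, sd}) and
48 eye-movement columns (3 conditions x 8 measures x {mean, sd}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MODALITIES = ("kinematic", "eye")
BLOCKS = ("general", "attention")
CONDITIONS = ("direct", "elevated", "direct-fast")
STATISTICS = ("mean", "sd")
META_FIELDS = ("modality", "block", "condition", "measure", "statistic")

GROUP_AUTISTIC = "autistic"
GROUP_CONTROL = "non-autistic"
GROUPS = (GROUP_AUTISTIC, GROUP_CONTROL)

#: The 20 per-movement kinematic base measures (means and SDs of these over
#: retained trials form the 40 features per condition).
KINEMATIC_MEASURES = (
    "duration",
    "peak_velocity",
    "mean_velocity",
    "pct_to_peak_velocity",
    "peak_acceleration",
    "pct_to_peak_acceleration",
    "peak_deceleration",
    "pct_to_peak_deceleration",
    "mean_abs_acceleration",
    "peak_jerk",
    "pct_to_peak_jerk",
    "mean_squared_jerk",
    "normalized_jerk",
    "vertical_amplitude",
    "pct_to_peak_height",
    "horizontal_amplitude",
    "path_length",
    "straightness_ratio",
    "n_velocity_peaks",
    "deceleration_fraction",
)

#: The 8 per-trial eye-movement base measures.
EYE_MEASURES = (
    "saccade_count",
    "saccade_amplitude",
    "saccade_duration",
    "saccade_peak_velocity",
    "first_saccade_latency",
    "fixation_duration",
    "pct_dwell_on_finger",
    "gaze_finger_distance",
)

_MEASURES_BY_MODALITY = {"kinematic": KINEMATIC_MEASURES, "eye": EYE_MEASURES}


class FeatureMatrixFormatError(ValueError):
    """Raised when a feature-matrix CSV does not follow the expected dialect."""


def feature_id(modality: str, block: str, condition: str, measure: str,
               statistic: str) -> str:
    """Build the canonical column identifier ``modality:block:condition:measure:stat``."""
    return f"{modality}:{block}:{condition}:{measure}:{statistic}"


def parse_feature_id(fid: str) -> dict:
    parts = fid.split(":")
    if len(parts) != 5:
        raise FeatureMatrixFormatError(
            f"feature id {fid!r} does not have the five "
            "modality:block:condition:measure:statistic components"
        )
    return dict(zip(META_FIELDS, parts))


def feature_universe(blocks=BLOCKS, modalities=MODALITIES) -> list[str]:
    """Canonical ordered list of feature ids for the requested blocks/modalities.

    Order: block, then modality (kinematic before eye), then condition,
    measure, statistic.  One block with both modalities yields 168 ids.
    """
    ids = []
    for block in blocks:
        for modality in modalities:
            for condition in CONDITIONS:
                for measure in _MEASURES_BY_MODALITY[modality]:
                    for stat in STATISTICS:
                        ids.append(feature_id(modality, block, condition, measure, stat))
    return ids


def meta_for_ids(ids) -> pd.DataFrame:
    """Per-feature metadata table (index = feature id) parsed from the ids."""
    rows = [parse_feature_id(fid) for fid in ids]
    return pd.DataFrame(rows, index=list(ids), columns=list(META_FIELDS))


@dataclass
class FeatureMatrix:
    """Samples x features values with labels and per-feature metadata.

    Parameters
    ----------
    values
        Real-valued frame, index = sample ids, columns = feature ids.
    labels
        Group label per sample, aligned with ``values.index``.
    feature_meta
        One row per feature with the :data:`META_FIELDS` columns; derived
        from the feature ids when omitted.
    """

    values: pd.DataFrame
    labels: pd.Series
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.feature_meta is None:
            self.feature_meta = meta_for_ids(self.values.columns)
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValueError("every sample needs a group label")
        if len(set(self.values.columns)) != self.values.shape[1]:
            raise ValueError("feature identifiers must be unique")
        if list(self.feature_meta.index) != list(self.values.columns):
            raise ValueError("feature_meta rows must match value columns")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) with y = 1 for the autistic class, 0 otherwise."""
        X = self.values.to_numpy(dtype=float)
        y = (self.labels.to_numpy() == GROUP_AUTISTIC).astype(int)
        return X, y

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.labels.copy(),
                             self.feature_meta.copy())

    def select(self, block: str | None = None, modality: str | None = None,
               condition: str | None = None) -> "FeatureMatrix":
        """Column subset by metadata; row set unchanged."""
        mask = pd.Series(True, index=self.feature_meta.index)
        for field, value in (("block", block), ("modality", modality),
                             ("condition", condition)):
            if value is not None:
                mask &= self.feature_meta[field] == value
        cols = list(self.feature_meta.index[mask])
        return FeatureMatrix(self.values[cols], self.labels,
                             self.feature_meta.loc[cols])

    def with_labels(self, labels) -> "FeatureMatrix":
        labels = pd.Series(np.asarray(labels), index=self.values.index,
                           name=self.labels.name)
        return FeatureMatrix(self.values, labels, self.feature_meta)

    def concat_features(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not self.values.index.equals(other.values.index):
            raise ValueError("sample sets differ; cannot combine modalities")
        return FeatureMatrix(pd.concat([self.values, other.values], axis=1),
                             self.labels,
                             pd.concat([self.feature_meta, other.feature_meta]))

    # -- CSV dialect -----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the 5-row metadata header followed by the data rows."""
        with open(path, "w", encoding="utf-8") as fh:
            for field in META_FIELDS:
                cells = [field, ""] + [str(v) for v in self.feature_meta[field]]
                fh.write(",".join(cells) + "\n")
            fh.write(",".join(["sample_id", "group"] + self.feature_ids) + "\n")
            for sid in self.sample_ids:
                row = self.values.loc[sid]
                cells = [str(sid), str(self.labels.loc[sid])] + [
                    "" if pd.isna(v) else repr(float(v)) for v in row
                ]
                fh.write(",".join(cells) + "\n")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        try:
            meta_raw = pd.read_csv(path, header=None, nrows=len(META_FIELDS),
                                   dtype=str, keep_default_na=False)
            data = pd.read_csv(path, skiprows=len(META_FIELDS))
        except Exception as exc:  # malformed layout
            raise FeatureMatrixFormatError(f"cannot parse {path}: {exc}") from exc
        if list(meta_raw[0]) != list(META_FIELDS):
            raise FeatureMatrixFormatError(
                f"{path}: expected metadata rows {META_FIELDS}, "
                f"found {tuple(meta_raw[0])}"
            )
        if data.columns[0] != "sample_id" or data.columns[1] != "group":
            raise FeatureMatrixFormatError(
                f"{path}: first data columns must be sample_id,group "
                f"(found {list(data.columns[:2])})"
            )
        fids = list(data.columns[2:])
        meta = pd.DataFrame(
            {field: list(meta_raw.iloc[i, 2:2 + len(fids)])
             for i, field in enumerate(META_FIELDS)},
            index=fids,
        )
        values = data.set_index("sample_id")[fids].astype(float)
        for col in fids:
            if not np.issubdtype(values[col].dtype, np.number):
                raise FeatureMatrixFormatError(f"{path}: column {col} is not numeric")
        labels = data.set_index("sample_id")["group"]
        return cls(values, labels, meta)
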