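"""File formats and validated readers/writers.

All on-disk formats are plain text: CSV (UTF-8, comma separator, '.'
decimal, missing values as empty fields) and JSON.  Frames are 0-based,
segment intervals half-open, angles in degrees.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    STATES,
    FaceTemplate,
    HeadAngleSeries,
    LandmarkTrajectory,
    SegmentAnnotation,
    StateProbSeries,
)

__all__ = [
    "read_template",
    "write_template",
    "read_landmarks",
    "write_landmarks",
    "read_angles",
    "write_angles",
    "read_states",
    "write_states",
    "read_segments",
    "write_segments",
    "read_features",
    "write_features",
    "read_cohort",
]

VALID_GROUPS = {"cervical", "generalised", "control"}
VALID_CONDITIONS = {"pre", "post"}


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_template(path) -> FaceTemplate:
    """Template CSV: landmark_id,x,y,z."""
    df = pd.read_csv(path)
    _require_columns(df, ["landmark_id", "x", "y", "z"], path)
    df = df.sort_values("landmark_id")
    return FaceTemplate(
        ids=df["landmark_id"].to_numpy(), coords=df[["x", "y", "z"]].to_numpy()
    )


def write_template(template: FaceTemplate, path) -> None:
    template.to_frame().to_csv(path, index=False)


def read_landmarks(path, fps: float) -> LandmarkTrajectory:
    """Landmark CSV: frame,landmark_id,x,y,z (0-based frames).

    Frames absent from the file are marked missing (NaN), never dropped.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "landmark_id", "x", "y", "z"], path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty landmark file")
    ids = np.sort(df["landmark_id"].unique())
    n_frames = int(df["frame"].max()) + 1
    coords = np.full((n_frames, len(ids), 3), np.nan)
    id_pos = {lid: k for k, lid in enumerate(ids)}
    fr = df["frame"].to_numpy(dtype=int)
    lm = df["landmark_id"].map(id_pos).to_numpy(dtype=int)
    coords[fr, lm, 0] = df["x"].to_numpy()
    coords[fr, lm, 1] = df["y"].to_numpy()
    coords[fr, lm, 2] = df["z"].to_numpy()
    return LandmarkTrajectory(fps=fps, ids=ids, coords=coords)


def write_landmarks(traj: LandmarkTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_angles(path, fps: float) -> HeadAngleSeries:
    """Angle CSV: frame,yaw_deg,tilt_deg,pitch_deg."""
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "yaw_deg", "tilt_deg", "pitch_deg"], path)
    df = df.sort_values("frame")
    return HeadAngleSeries(
        fps=fps,
        yaw=df["yaw_deg"].to_numpy(),
        tilt=df["tilt_deg"].to_numpy(),
        pitch=df["pitch_deg"].to_numpy(),
    )


def write_angles(angles: HeadAngleSeries, path) -> None:
    angles.to_frame().to_csv(path, index=False)


def read_states(path, fps: float) -> StateProbSeries:
    """State CSV: frame plus one probability column per movement state."""
    df = pd.read_csv(path)
    _require_columns(df, ["frame", *STATES], path)
    df = df.sort_values("frame").reset_index(drop=True)
    return StateProbSeries(fps=fps, probs=df[list(STATES)])


def write_states(states: StateProbSeries, path) -> None:
    out = states.probs.copy()
    out.insert(0, "frame", np.arange(len(out)))
    out.to_csv(path, index=False)


def read_segments(path) -> SegmentAnnotation:
    """Segments JSON: [{"label": str, "start": int, "end": int}, ...]."""
    with open(path) as fh:
        records = json.load(fh)
    return SegmentAnnotation(records)


def write_segments(segments: SegmentAnnotation, path) -> None:
    with open(path, "w") as fh:
        json.dump(segments.to_records(), fh, indent=1)


def read_features(path) -> pd.DataFrame:
    """Tidy feature CSV: recording_id,feature,value,unit,missing_reason."""
    df = pd.read_csv(path)
    _require_columns(df, ["recording_id", "feature", "value"], path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty feature file")
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False)


def features_wide(features: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy feature table into recordings x features."""
    return features.pivot_table(
        index="recording_id", columns="feature", values="value", aggfunc="first"
    )


def read_cohort(manifest_path, features_path) -> pd.DataFrame:
    """Join a cohort manifest with a tidy feature table into a CohortTable.

    Manifest CSV columns: recording_id, subject_id, condition (pre/post),
    group (cervical/generalised/control), plus any clinical score columns.
    Duplicate (subject, condition) rows and unknown group labels are
    reported with their row numbers.
    """
    manifest = pd.read_csv(manifest_path)
    _require_columns(
        manifest, ["recording_id", "subject_id", "condition", "group"], manifest_path
    )
    bad_group = manifest[~manifest["group"].isin(VALID_GROUPS)]
    if len(bad_group):
        raise ValueError(
            f"{manifest_path}: unknown group labels "
            f"{sorted(bad_group['group'].unique())} at rows "
            f"{[int(i) + 2 for i in bad_group.index]}"  # 1-based incl. header
        )
    bad_cond = manifest[~manifest["condition"].isin(VALID_CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"{manifest_path}: unknown condition labels "
            f"{sorted(bad_cond['condition'].unique())} at rows "
            f"{[int(i) + 2 for i in bad_cond.index]}"
        )
    dupes = manifest[manifest.duplicated(["subject_id", "condition"], keep=False)]
    if len(dupes):
        raise ValueError(
            f"{manifest_path}: duplicate (subject, condition) rows "
            f"{[int(i) + 2 for i in dupes.index]}"
        )
    feats = read_features(features_path)
    wide = features_wide(feats)
    cohort = manifest.merge(
        wide, how="left", left_on="recording_id", right_index=True
    )
    return cohort
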