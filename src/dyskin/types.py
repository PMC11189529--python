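"""Core domain types shared across the pipeline.

Conventions used everywhere in this package:

* frames are 0-based integers, intervals are half-open ``[start, end)``;
* angles are degrees, signed, wrapped to ``(-180, 180]``;
* time is seconds; sampling rate ``fps`` is frames per second;
* the head-angle axes are named after the dystonic deviation they measure:
  ``yaw`` (torticollis, rotation), ``tilt`` (laterocollis, lateral flexion)
  and ``pitch`` (antero-/retrocollis, sagittal flexion/extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The seven per-frame head movement states, in canonical column order.
STATES: tuple[str, ...] = (
    "face_forward",
    "rotation_left",
    "rotation_right",
    "tilt_left",
    "tilt_right",
    "anterocollis",
    "retrocollis",
)

#: Angle axes in canonical order (also the dominant-axis tie-break order).
AXES: tuple[str, ...] = ("yaw", "tilt", "pitch")

#: Clinical deviation name per axis.
AXIS_CLINICAL: dict[str, str] = {
    "yaw": "torticollis",
    "tilt": "laterocollis",
    "pitch": "anteroretrocollis",
}

#: Opposing state pair per motion axis; the first member is the
#: left / antero direction (positive side of the symmetry index).
AXIS_STATE_PAIRS: dict[str, tuple[str, str]] = {
    "rotation": ("rotation_left", "rotation_right"),
    "tilt": ("tilt_left", "tilt_right"),
    "pitch": ("anterocollis", "retrocollis"),
}


def wrap_degrees(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-180, 180]."""
    return -((180.0 - np.asarray(a, dtype=float)) % 360.0 - 180.0)


@dataclass(frozen=True)
class FaceTemplate:
    """A rigid face-forward landmark template in arbitrary rigid-body units.

    The template plays the role of the neutral "face-forward face mask":
    per-frame rotations are estimated against it.  Coordinates are centred
    on their centroid at construction and must span 3-D space (at least 4
    non-coplanar points), otherwise the rotation is unrecoverable.
    """

    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("template coordinates must be (n, 3)")
        if len(ids) != len(coords):
            raise ValueError("ids and coordinates length mismatch")
        if len(coords) < 4:
            raise ValueError(
                "a face template needs >= 4 landmarks to determine a rotation"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("template coordinates must be finite")
        coords = coords - coords.mean(axis=0)
        if np.linalg.matrix_rank(coords, tol=1e-9 * max(1.0, np.abs(coords).max())) < 3:
            raise ValueError("template landmarks are coplanar (rank < 3)")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)

    @property
    def n_landmarks(self) -> int:
        return len(self.ids)

    @property
    def radius(self) -> float:
        """RMS distance of landmarks from the centroid (the template scale)."""
        return float(np.sqrt(np.mean(np.sum(self.coords**2, axis=1))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "landmark_id": self.ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


@dataclass
class LandmarkTrajectory:
    """Per-frame 3-D landmark coordinates at a fixed frame rate.

    ``coords`` has shape (frames, landmarks, 3).  Missing frames are marked
    by NaN coordinates, never silently dropped.
    """

    fps: float
    ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must be (frames, landmarks, 3)")
        if self.coords.shape[1] != len(self.ids):
            raise ValueError("landmark count does not match ids")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of frames with any non-finite coordinate."""
        return ~np.isfinite(self.coords).all(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        n_f, n_l, _ = self.coords.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_l),
                "landmark_id": np.tile(self.ids, n_f),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
                "z": self.coords[:, :, 2].ravel(),
            }
        )


@dataclass
class HeadAngleSeries:
    """Signed per-frame head angles (degrees) on the three deviation axes."""

    fps: float
    yaw: np.ndarray
    tilt: np.ndarray
    pitch: np.ndarray

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.tilt = np.asarray(self.tilt, dtype=float)
        self.pitch = np.asarray(self.pitch, dtype=float)
        if not (len(self.yaw) == len(self.tilt) == len(self.pitch)):
            raise ValueError("axis series must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.yaw)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise KeyError(f"unknown axis {name!r}; expected one of {AXES}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "yaw_deg": self.yaw,
                "tilt_deg": self.tilt,
                "pitch_deg": self.pitch,
            }
        )


@dataclass
class StateProbSeries:
    """Per-frame probabilities for the seven head movement states.

    Values live in [0, 1] but do NOT have to sum to one across states: the
    upstream classifier is multilabel, so several states may be probable at
    once and correlations between state traces are meaningful.
    """

    fps: float
    probs: pd.DataFrame

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        missing = [s for s in STATES if s not in self.probs.columns]
        if missing:
            raise ValueError(f"state columns missing: {missing}")
        self.probs = self.probs.loc[:, list(STATES)].astype(float).reset_index(drop=True)
        vals = self.probs.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("state probabilities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.probs)

    def trace(self, state: str) -> np.ndarray:
        return self.probs[state].to_numpy()


@dataclass(frozen=True)
class Segment:
    """A labelled half-open frame interval [start, end)."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


class SegmentAnnotation:
    """An ordered collection of labelled frame segments."""

    def __init__(self, segments: Iterable[Segment | dict]):
        self.segments: list[Segment] = [
            s if isinstance(s, Segment) else Segment(s["label"], s["start"], s["end"])
            for s in segments
        ]

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def select(self, label: str) -> list[Segment]:
        return [s for s in self.segments if s.label == label]

    def frames(self, label: str, n_frames: int | None = None) -> np.ndarray:
        """All frame indices carrying ``label`` (clipped to n_frames if given)."""
        idx: list[np.ndarray] = []
        for s in self.select(label):
            end = s.end if n_frames is None else min(s.end, n_frames)
            idx.append(np.arange(s.start, end))
        if not idx:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate(idx))

    def to_records(self) -> list[dict]:
        return [
            {"label": s.label, "start": int(s.start), "end": int(s.end)}
            for s in self.segments
        ]


def feature_table(
    entries: Sequence[tuple[str, float | None, str, str | None]],
    recording_id: str | None = None,
) -> pd.DataFrame:
    """Assemble a tidy feature table from (feature, value, unit, missing_reason).

    Missing values are stored as NaN with a textual ``missing_reason``.
    """
    rows = []
    for name, value, unit, reason in entries:
        rows.append(
            {
                "recording_id": recording_id,
                "feature": name,
                "value": np.nan if value is None else float(value),
                "unit": unit,
                "missing_reason": reason,
            }
        )
    df = pd.DataFrame(
        rows, columns=["recording_id", "feature", "value", "unit", "missing_reason"]
    )
    if recording_id is None:
        df = df.drop(columns=["recording_id"])
    return df
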