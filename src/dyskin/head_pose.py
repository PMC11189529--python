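"""Head-pose angles from landmark trajectories via orthogonal Procrustes.

Per frame, the proper rotation best aligning the face-forward template with
the observed landmarks (least squares, no scaling, no reflection) is
estimated and decomposed into the three clinical deviation angles.

Coordinate frame and Euler convention
-------------------------------------
Right-handed axes fixed to the camera: ``x`` to the subject's anatomical
left, ``y`` superior, ``z`` anterior (toward the camera).  Rotations are
intrinsic, applied yaw (about y), then pitch (about x), then tilt/roll
(about z).  Signs: yaw > 0 rotates the nose toward the subject's left
(torticollis left), pitch > 0 is flexion (anterocollis), tilt > 0 brings
the left ear toward the left shoulder (laterocollis left).  The analyses
downstream use magnitudes and within-convention contrasts, so any fixed,
documented convention is equivalent; this one is enforced package-wide.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .types import (
    AXES,
    FaceTemplate,
    HeadAngleSeries,
    LandmarkTrajectory,
    Segment,
    SegmentAnnotation,
    wrap_degrees,
)

__all__ = [
    "estimate_rotation",
    "angles_to_rotation",
    "rotation_to_angles",
    "track_head_angles",
    "static_deviation",
    "dominant_axis",
    "GimbalWarning",
]

#: |pitch| closer than this (degrees) to 90 is flagged gimbal-degenerate.
GIMBAL_MARGIN_DEG = 0.5


class GimbalWarning(UserWarning):
    """Euler decomposition near gimbal lock (|pitch| ~ 90 deg)."""


def estimate_rotation(
    frame_landmarks: np.ndarray, template: FaceTemplate
) -> np.ndarray:
    """Proper rotation R minimising ||R @ template - landmarks||_F.

    Both point sets are centred internally; scale is never fitted (monocular
    mesh scale is arbitrary) and reflections are corrected to the nearest
    proper rotation by flipping the smallest singular vector.

    Parameters
    ----------
    frame_landmarks : (n, 3) array
        Observed landmark coordinates for one frame, ordered like the
        template.
    template : FaceTemplate
        Face-forward reference landmarks.

    Returns
    -------
    (3, 3) ndarray with ``det R = +1`` such that ``R @ template.coords[i]``
    approximates the centred observed landmark ``i``.
    """
    obs = np.asarray(frame_landmarks, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("frame landmarks must be (n, 3)")
    if obs.shape[0] != template.n_landmarks:
        raise ValueError(
            f"landmark count {obs.shape[0]} does not match template "
            f"({template.n_landmarks})"
        )
    if obs.shape[0] < 4:
        raise ValueError("need >= 4 landmarks to estimate a rotation")
    if not np.all(np.isfinite(obs)):
        raise ValueError("non-finite landmark coordinates")
    obs = obs - obs.mean(axis=0)
    # cross-covariance of observed vs template points
    H = obs.T @ template.coords
    U, s, Vt = np.linalg.svd(H)
    if s[-1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("rank-deficient landmark configuration")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def angles_to_rotation(yaw: float, tilt: float, pitch: float) -> np.ndarray:
    """Compose a rotation matrix from (yaw, tilt, pitch) in degrees.

    Inverse of :func:`rotation_to_angles` under the module convention
    (intrinsic Y-X-Z; the tilt sign is negated so that tilt > 0 is
    laterocollis toward the subject's left).
    """
    return Rotation.from_euler(
        "YXZ", [yaw, pitch, -tilt], degrees=True
    ).as_matrix()


def rotation_to_angles(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose a proper rotation into (yaw, tilt, pitch) degrees.

    Raises a :class:`GimbalWarning` via ``warnings`` when |pitch| is within
    0.5 degrees of +-90, where yaw and tilt are no longer separable.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation")
    yaw, pitch, neg_tilt = Rotation.from_matrix(R).as_euler("YXZ", degrees=True)
    if abs(abs(pitch) - 90.0) < GIMBAL_MARGIN_DEG:
        import warnings

        warnings.warn(
            f"pitch {pitch:.3f} deg is within {GIMBAL_MARGIN_DEG} deg of gimbal "
            "lock; yaw/tilt are ill-determined",
            GimbalWarning,
            stacklevel=2,
        )
    return float(yaw), float(-neg_tilt), float(pitch)


def _interpolate_gaps(series: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap frames."""
    out = series.copy()
    isnan = ~np.isfinite(out)
    if not isnan.any():
        return out
    n = len(out)
    idx = np.arange(n)
    valid = idx[~isnan]
    if valid.size == 0:
        return out
    # locate NaN runs
    starts = np.flatnonzero(isnan & ~np.r_[False, isnan[:-1]])
    for s in starts:
        e = s
        while e < n and isnan[e]:
            e += 1
        if s == 0 or e == n:  # leading/trailing gaps stay missing
            continue
        if e - s <= max_gap:
            out[s:e] = np.interp(idx[s:e], [s - 1, e], [out[s - 1], out[e]])
    return out


def track_head_angles(
    traj: LandmarkTrajectory, template: FaceTemplate
) -> HeadAngleSeries:
    """Per-frame head angles for a whole trajectory.

    Frames marked missing (NaN coordinates) yield missing angles; interior
    gaps no longer than 0.5 s are linearly interpolated, longer gaps stay
    missing.
    """
    if not np.array_equal(traj.ids, template.ids):
        raise ValueError("trajectory landmark ids do not match template")
    missing = traj.missing_mask()
    if missing.all():
        raise ValueError("all frames are missing; nothing to track")
    n = traj.n_frames
    out = np.full((n, 3), np.nan)
    for t in range(n):
        if missing[t]:
            continue
        R = estimate_rotation(traj.coords[t], template)
        out[t] = rotation_to_angles(R)
    max_gap = int(round(0.5 * traj.fps))
    for k in range(3):
        out[:, k] = _interpolate_gaps(out[:, k], max_gap)
    return HeadAngleSeries(fps=traj.fps, yaw=out[:, 0], tilt=out[:, 1], pitch=out[:, 2])


def static_deviation(
    angles: HeadAngleSeries,
    segments: SegmentAnnotation,
    label: str = "null_position",
    min_duration_s: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Static head-angle deviation from face-forward in the null position.

    The signed deviation per axis is the median angle over all frames in
    ``label`` segments (the median is robust to tremor excursions riding on
    the tonic posture); the absolute deviation is its magnitude.

    Returns
    -------
    dict mapping axis -> (signed_deg, absolute_deg).

    Raises
    ------
    ValueError
        If no segment carries ``label`` (distinct message), or the labelled
        frames span less than ``min_duration_s`` seconds or are all missing.
    """
    segs = segments.select(label)
    if not segs:
        raise ValueError(f"no {label!r} segment annotated")
    frames = segments.frames(label, angles.n_frames)
    if frames.size < min_duration_s * angles.fps:
        raise ValueError(
            f"{label!r} segments cover {frames.size} frames; "
            f"need >= {min_duration_s} s at {angles.fps} fps"
        )
    out: dict[str, tuple[float, float]] = {}
    for ax in AXES:
        vals = angles.axis(ax)[frames]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"all {label!r} frames missing on axis {ax}")
        signed = float(np.median(vals))
        out[ax] = (signed, abs(signed))
    return out


def dominant_axis(static: dict[str, tuple[float, float]] | dict[str, float]) -> str:
    """Axis of maximal absolute static deviation.

    Ties break deterministically in the fixed order yaw (torticollis) >
    tilt (laterocollis) > pitch (anteroretrocollis).
    """
    mags = {}
    for ax in AXES:
        v = static[ax]
        mags[ax] = abs(v[1]) if isinstance(v, tuple) else abs(float(v))
    best = max(AXES, key=lambda ax: (mags[ax], -AXES.index(ax)))
    return best
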