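"""Synthetic generators with planted ground truth.

Every downstream stage of the pipeline is testable against data generated
here: rigid head-rotation angle series with tonic deviations, 2-10 Hz
tremor with optional phase-locked harmonics and slow drift; landmark
trajectories rendered from those angles; movement-state probability traces
with plantable inter-state (overflow) correlations; and cohort tables with
planted pre/post and between-group effects plus clinical-style scores.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .head_pose import angles_to_rotation
from .types import (
    AXES,
    STATES,
    FaceTemplate,
    HeadAngleSeries,
    LandmarkTrajectory,
    Segment,
    SegmentAnnotation,
    StateProbSeries,
)

__all__ = [
    "make_template_face",
    "TremorSpec",
    "MotionSpec",
    "simulate_angle_series",
    "render_landmarks",
    "simulate_state_probs",
    "GroupSpec",
    "CohortSpec",
    "simulate_cohort",
]

# Stylised face landmarks in canonical face-forward pose, rigid-body units.
# x: subject's left, y: superior, z: anterior.  Deliberately non-coplanar.
_BASE_FACE = np.array(
    [
        [0.0, 0.0, 1.0],  # nose apex
        [0.0, -1.0, 0.3],  # chin
        [0.0, 0.9, 0.4],  # forehead (glabella)
        [0.55, 0.35, 0.2],  # left eye outer corner
        [-0.55, 0.35, 0.2],  # right eye outer corner
        [0.8, -0.2, -0.3],  # left cheek/ear
        [-0.8, -0.2, -0.3],  # right cheek/ear
        [0.3, -0.6, 0.5],  # left mouth corner
        [-0.3, -0.6, 0.5],  # right mouth corner
        [0.0, 0.45, 0.8],  # nose bridge
        [0.45, 0.75, 0.1],  # left brow
        [-0.45, 0.75, 0.1],  # right brow
    ]
)


def make_template_face(n_landmarks: int = 12) -> FaceTemplate:
    """Deterministic stylised face template with ``n_landmarks`` points.

    The first 12 landmarks are hand-placed facial fiducials (nose, chin,
    eyes, cheeks, mouth, brows); beyond 12, additional points are drawn on
    a face-like ellipsoid from a fixed internal seed so that two calls with
    the same ``n_landmarks`` are identical.
    """
    if n_landmarks < 4:
        raise ValueError("need >= 4 landmarks for a recoverable rotation")
    if n_landmarks <= len(_BASE_FACE):
        coords = _BASE_FACE[:n_landmarks].copy()
    else:
        rng = np.random.default_rng(20230515)  # fixed: template is not random
        extra = n_landmarks - len(_BASE_FACE)
        u = rng.uniform(-np.pi / 2, np.pi / 2, size=extra)
        v = rng.uniform(-np.pi / 3, np.pi / 2, size=extra)
        pts = np.column_stack(
            [0.85 * np.sin(u) * np.cos(v), 0.95 * np.sin(v), 0.75 * np.cos(u) * np.cos(v)]
        )
        coords = np.vstack([_BASE_FACE, pts])
    return FaceTemplate(ids=np.arange(n_landmarks), coords=coords)


@dataclass(frozen=True)
class TremorSpec:
    """Oscillatory component on one axis.

    f0 is the fundamental frequency (Hz, inside the 2-10 Hz analysis band),
    amplitude the sinusoid amplitude in degrees, harmonic_ratio the relative
    amplitude of the first harmonic at 2*f0 (0 disables it), and
    harmonic_phase_locked whether the harmonic phase is 2x the fundamental
    phase (locked) or drifts independently.
    """

    f0: float
    amplitude: float
    harmonic_ratio: float = 0.0
    harmonic_phase_locked: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.harmonic_ratio < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.amplitude > 0 and not (2.0 <= self.f0 <= 10.0):
            raise ValueError("tremor f0 must lie in [2, 10] Hz")


@dataclass(frozen=True)
class MotionSpec:
    """Generating parameters for one synthetic head-angle recording."""

    duration_s: float = 60.0
    fps: float = 30.0
    tonic_deviation: dict[str, float] = field(default_factory=dict)
    tremor: dict[str, TremorSpec] = field(default_factory=dict)
    drift_amplitude: float = 0.0
    angle_noise_sd: float = 0.0
    landmark_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration must be positive")
        if self.drift_amplitude < 0 or self.angle_noise_sd < 0 or self.landmark_noise_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for ax in list(self.tonic_deviation) + list(self.tremor):
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}")


def _slow_drift(n: int, fps: float, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (< 0.5 Hz) wander with SD ~ amplitude degrees.

    Modelled as white noise low-passed at 0.4 Hz and rescaled, so the
    2-10 Hz analysis band rejects it entirely — the analogue of slow camera
    movement or patient swaying.
    """
    if amplitude == 0 or n < 20:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(4, 0.4, btype="low", fs=fps, output="sos")
    slow = sps.sosfiltfilt(sos, white)
    sd = slow.std()
    if sd < 1e-12:
        return np.zeros(n)
    return amplitude * slow / sd


def simulate_angle_series(spec: MotionSpec) -> tuple[HeadAngleSeries, dict]:
    """Generate per-axis head angles and the ground-truth record.

    Per axis: angle(t) = tonic + drift + A*sin(2*pi*f0*t + phi)
    [+ A*ratio*sin(2*(2*pi*f0*t + phi)) when the harmonic is phase-locked,
    or with an independently drifting phase otherwise] + white noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    series: dict[str, np.ndarray] = {}
    truth: dict = {"fps": spec.fps, "n_frames": n, "axes": {}}
    for ax in AXES:
        tonic = float(spec.tonic_deviation.get(ax, 0.0))
        x = np.full(n, tonic)
        drift = _slow_drift(n, spec.fps, spec.drift_amplitude, rng)
        x = x + drift
        ax_truth: dict = {"tonic": tonic, "drift_amplitude": spec.drift_amplitude}
        trem = spec.tremor.get(ax)
        if trem is not None and trem.amplitude > 0:
            phi = rng.uniform(0, 2 * np.pi)
            fundamental_phase = 2 * np.pi * trem.f0 * t + phi
            x = x + trem.amplitude * np.sin(fundamental_phase)
            if trem.harmonic_ratio > 0:
                if trem.harmonic_phase_locked:
                    harm_phase = 2.0 * fundamental_phase
                else:
                    # independent narrowband phase: own offset + slow wander
                    wander = np.cumsum(rng.standard_normal(n)) * (0.6 / np.sqrt(spec.fps))
                    harm_phase = (
                        2 * np.pi * (2 * trem.f0) * t + rng.uniform(0, 2 * np.pi) + wander
                    )
                x = x + trem.amplitude * trem.harmonic_ratio * np.sin(harm_phase)
            ax_truth["tremor"] = {
                "f0": trem.f0,
                "amplitude": trem.amplitude,
                "harmonic_ratio": trem.harmonic_ratio,
                "harmonic_phase_locked": trem.harmonic_phase_locked,
                "phase": phi,
            }
        if spec.angle_noise_sd > 0:
            x = x + rng.standard_normal(n) * spec.angle_noise_sd
        ax_truth["angle_noise_sd"] = spec.angle_noise_sd
        series[ax] = x
        truth["axes"][ax] = ax_truth
    angles = HeadAngleSeries(fps=spec.fps, yaw=series["yaw"], tilt=series["tilt"], pitch=series["pitch"])
    return angles, truth


def render_landmarks(
    angles: HeadAngleSeries,
    template: FaceTemplate,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LandmarkTrajectory:
    """Rotate the template by the per-frame angles and add isotropic noise.

    Frame t landmarks are R(t) @ template plus N(0, noise_sd^2) per
    coordinate, with R(t) composed under the package Euler convention; at
    zero noise the round trip through head-pose tracking recovers the
    generating angles.  ``noise_sd`` is in template units (compare against
    ``template.radius``).
    """
    for ax in AXES:
        if not np.all(np.isfinite(angles.axis(ax))):
            raise ValueError("cannot render non-finite angles")
    rng = np.random.default_rng(seed)
    n = angles.n_frames
    coords = np.empty((n, template.n_landmarks, 3))
    for i in range(n):
        R = angles_to_rotation(angles.yaw[i], angles.tilt[i], angles.pitch[i])
        coords[i] = template.coords @ R.T
    if noise_sd > 0:
        coords = coords + rng.standard_normal(coords.shape) * noise_sd
    return LandmarkTrajectory(fps=angles.fps, ids=template.ids.copy(), coords=coords)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def simulate_state_probs(
    angles: HeadAngleSeries,
    overflow: np.ndarray | None = None,
    threshold_deg: float = 10.0,
    softness: float = 5.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> StateProbSeries:
    """Emulate frame-wise movement-state classifier outputs from angles.

    Directional state probabilities follow a logistic soft threshold on the
    signed angle exceedance (e.g. rotation_left turns on as yaw exceeds
    ``threshold_deg``, over a scale of ``softness`` degrees); face_forward
    is high when all three angles are small.  The optional 7x7 ``overflow``
    matrix linearly mixes the traces (column j of the output is a weighted
    sum of raw traces) to plant inter-state correlations — the synthetic
    analogue of dystonic overflow.  Outputs are clipped to [0, 1] and carry
    no sum-to-one constraint (multilabel classifier).
    """
    rng = np.random.default_rng(seed)
    if softness <= 0:
        raise ValueError("softness must be positive")
    raw = {}
    signed = {
        "rotation_left": angles.yaw,
        "rotation_right": -angles.yaw,
        "tilt_left": angles.tilt,
        "tilt_right": -angles.tilt,
        "anterocollis": angles.pitch,
        "retrocollis": -angles.pitch,
    }
    for state, a in signed.items():
        raw[state] = _sigmoid((a - threshold_deg) / softness)
    max_abs = np.max(
        np.abs(np.column_stack([angles.yaw, angles.tilt, angles.pitch])), axis=1
    )
    raw["face_forward"] = _sigmoid((threshold_deg - max_abs) / softness)
    P = np.column_stack([raw[s] for s in STATES])
    if overflow is not None:
        overflow = np.asarray(overflow, dtype=float)
        if overflow.shape != (len(STATES), len(STATES)):
            raise ValueError(f"overflow matrix must be {len(STATES)}x{len(STATES)}")
        if overflow.min() < 0 or overflow.max() > 1:
            raise ValueError("overflow weights must lie in [0, 1]")
        P = P @ overflow
    if noise_sd > 0:
        P = P + rng.standard_normal(P.shape) * noise_sd
    P = np.clip(P, 0.0, 1.0)
    return StateProbSeries(fps=angles.fps, probs=pd.DataFrame(P, columns=list(STATES)))


def default_segments(n_frames: int, fps: float, null_fraction: float = 0.2) -> SegmentAnnotation:
    """A single leading null-position segment covering ``null_fraction`` of the recording."""
    end = max(int(round(null_fraction * n_frames)), int(round(fps)) + 1)
    return SegmentAnnotation([Segment("null_position", 0, min(end, n_frames))])


# ---------------------------------------------------------------------------
# Cohort-level simulation


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group with planted effect structure.

    prepost_shifts: per-feature pre-minus-post shift in SD units (positive =
    larger pre-operatively), applied in full to responders and scaled by
    ``nonresponder_attenuation`` for non-responders.  between_shifts: per
    feature additive offset (SD units) for this group relative to the
    reference, planting between-group contrasts.
    """

    name: str
    n_subjects: int
    conditions: tuple[str, ...] = ("pre", "post")
    prepost_shifts: dict[str, float] = field(default_factory=dict)
    between_shifts: dict[str, float] = field(default_factory=dict)
    responder_fraction: float = 1.0
    nonresponder_attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: groups, feature names, noise scale and seed."""

    groups: tuple[GroupSpec, ...]
    feature_names: tuple[str, ...]
    noise_sd: float = 1.0
    score_noise_sd: float = 0.0
    responder_improvement: float = 0.5
    nonresponder_improvement: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        if not self.feature_names:
            raise ValueError("need at least one feature")


_SUBSCORES = {  # ordinal clinical sub-items: (column, max value)
    "torticollis_score": 4,
    "laterocollis_score": 3,
    "anterocollis_score": 3,
    "retrocollis_score": 3,
    "tremor_score": 4,
}


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one feature vector per recording with planted effects.

    Paired pre/post rows share subject_id.  A latent severity per subject
    and condition drives the clinical columns: the total severity score
    (0-35 scale) improves by ``responder_improvement`` (relative) for
    responders and ``nonresponder_improvement`` for non-responders, and the
    ordinal sub-scores are monotone noisy functions of the same severity.
    Feature j of subject i is baseline + between-group shift + half the
    pre/post shift (sign by condition, attenuated for non-responders) +
    N(0, noise_sd^2) noise.

    Returns the cohort table and a ground-truth dict with planted shifts
    and responder labels.
    """
    rng = np.random.default_rng(spec.seed)
    feats = list(spec.feature_names)
    rows = []
    truth: dict = {"responders": {}, "groups": {}}
    for g in spec.groups:
        truth["groups"][g.name] = {
            "prepost_shifts": dict(g.prepost_shifts),
            "between_shifts": dict(g.between_shifts),
        }
        n_resp = int(round(g.responder_fraction * g.n_subjects))
        resp_flags = np.zeros(g.n_subjects, dtype=bool)
        resp_flags[:n_resp] = True
        rng.shuffle(resp_flags)
        for i in range(g.n_subjects):
            subject = f"{g.name}_{i:03d}"
            responder = bool(resp_flags[i])
            truth["responders"][subject] = responder
            baseline = rng.standard_normal(len(feats))
            severity_pre = rng.uniform(12, 30)
            improvement = (
                spec.responder_improvement if responder else spec.nonresponder_improvement
            )
            factor = 1.0 if responder else g.nonresponder_attenuation
            for cond in g.conditions:
                sign = {"pre": +0.5, "post": -0.5}.get(cond, 0.0)
                vals = baseline.copy()
                for j, f in enumerate(feats):
                    vals[j] += g.between_shifts.get(f, 0.0)
                    vals[j] += sign * factor * g.prepost_shifts.get(f, 0.0)
                vals += rng.standard_normal(len(feats)) * spec.noise_sd
                severity = severity_pre * (1 - improvement) if cond == "post" else severity_pre
                severity_obs = severity + (
                    rng.standard_normal() * spec.score_noise_sd if spec.score_noise_sd else 0.0
                )
                row = {
                    "recording_id": f"{subject}_{cond}",
                    "subject_id": subject,
                    "condition": cond,
                    "group": g.name,
                    "twstrs_total": float(np.clip(severity_obs, 0, 35)),
                }
                for col, mx in _SUBSCORES.items():
                    noisy = severity_obs / 35.0 * mx
                    if spec.score_noise_sd:
                        noisy += rng.standard_normal() * 0.3
                    row[col] = float(np.clip(np.round(noisy), 0, mx))
                row.update({f: vals[j] for j, f in enumerate(feats)})
                rows.append(row)
    cohort = pd.DataFrame(rows)
    return cohort, truth
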