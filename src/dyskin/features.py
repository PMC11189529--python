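"""Kinematic feature bank from head-angle and movement-state series.

Features computed over a full recording:

* dominant oscillation frequency and amplitude per axis (dystonic tremor),
  from a band-limited (2-10 Hz) averaged Fourier spectrogram;
* pairwise Pearson correlations between movement-state probability traces
  (a proxy for dystonic overflow) and their mean against face-forward;
* per-axis directional symmetry of time spent in opposing states;
* multiscale sample entropy of the angle series (movement complexity
  versus timescale);
* harmonic strength: distance correlation between the instantaneous phases
  of the dominant tremor frequency and its first harmonic (2*f0).

Sample entropy and distance correlation are implemented here from their
definitions (vectorised); the test suite checks them against brute-force
counting and an independent implementation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.spatial.distance import cdist, pdist

from .types import (
    AXES,
    AXIS_STATE_PAIRS,
    STATES,
    HeadAngleSeries,
    SegmentAnnotation,
    StateProbSeries,
    feature_table,
)
from . import head_pose

__all__ = [
    "bandpass",
    "dominant_oscillation",
    "state_correlation_matrix",
    "mean_forward_correlation",
    "occupancy_times",
    "symmetry_index",
    "sample_entropy",
    "multiscale_entropy",
    "default_mse_scales",
    "distance_correlation",
    "harmonic_strength",
    "extract_features",
]


def _clean(series: np.ndarray) -> np.ndarray:
    """Trim non-finite edges and linearly interpolate interior gaps."""
    x = np.asarray(series, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("series is entirely missing")
    first, last = np.flatnonzero(finite)[[0, -1]]
    x = x[first : last + 1]
    finite = np.isfinite(x)
    if not finite.all():
        idx = np.arange(len(x))
        x = np.interp(idx, idx[finite], x[finite])
    return x


def bandpass(
    series: np.ndarray,
    fps: float,
    low_hz: float = 2.0,
    high_hz: float = 10.0,
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    The default 2-10 Hz band isolates dystonic jerks and tremor while
    rejecting slow intended movements / camera sway below 2 Hz and tracking
    noise above 10 Hz.  When slow artifacts are absent a 1 Hz low cut can
    be used instead (``low_hz=1``).
    """
    if fps <= 2 * high_hz:
        raise ValueError(
            f"fps={fps} cannot resolve {high_hz} Hz (Nyquist {fps / 2} Hz); "
            "reduce high_hz or resample"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    x = np.asarray(series, dtype=float)
    if len(x) <= 3 * order:
        raise ValueError(f"series too short to filter (need > {3 * order} samples)")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fps, output="sos")
    return sps.sosfiltfilt(sos, x)


def _filter_gain(fps: float, low_hz: float, high_hz: float, order: int, f: float) -> float:
    """Amplitude gain of the zero-phase band-pass at frequency f."""
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fps, output="sos")
    _, h = sps.sosfreqz(sos, worN=[f], fs=fps)
    return float(np.abs(h[0]) ** 2)  # applied twice (forward + backward)


def dominant_oscillation(
    series: np.ndarray,
    fps: float,
    low_hz: float = 2.0,
    high_hz: float = 10.0,
    order: int = 6,
    window_s: float = 2.0,
    detect_ratio: float = 2.0,
) -> tuple[float, float]:
    """Primary in-band oscillation frequency (Hz) and amplitude (degrees).

    The band-passed trace is analysed with a Fourier spectrogram (Hann
    windows of ``window_s`` seconds, 50% overlap) whose spectra are
    averaged across windows.  The peak of the averaged spectrum inside
    [low_hz, high_hz] is refined by parabolic interpolation; the amplitude
    is the sinusoid-equivalent amplitude of the power integrated over the
    peak's main lobe (peak bin +-2 bins), compensated for the filter gain
    at the peak.

    A peak is only reported when it exceeds ``detect_ratio`` times the
    median in-band power; otherwise the trace is indistinguishable from a
    flat background and (nan, 0.0) is returned.  Constant series also give
    (nan, 0.0).
    """
    x = _clean(series)
    nperseg = int(round(window_s * fps))
    if len(x) < nperseg:
        raise ValueError(
            f"series shorter than one spectrogram window ({nperseg} frames)"
        )
    if np.ptp(x) == 0:
        return (np.nan, 0.0)
    filt = bandpass(x, fps, low_hz, high_hz, order)
    freqs, psd = sps.welch(
        filt,
        fs=fps,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    df = freqs[1] - freqs[0]
    band = (freqs >= low_hz) & (freqs <= high_hz)
    if band.sum() < 3:
        raise ValueError("spectral band too narrow at this resolution")
    band_idx = np.flatnonzero(band)
    k = band_idx[np.argmax(psd[band_idx])]
    peak = psd[k]
    floor = np.median(psd[band_idx])
    if floor <= 0 or peak < detect_ratio * floor:
        return (np.nan, 0.0)
    # parabolic (quadratic-in-log-power) refinement of the peak frequency
    f_hat = freqs[k]
    if 0 < k < len(freqs) - 1 and psd[k - 1] > 0 and psd[k + 1] > 0:
        a, b, c = np.log(psd[k - 1]), np.log(psd[k]), np.log(psd[k + 1])
        denom = a - 2 * b + c
        if denom < 0:
            f_hat = freqs[k] + 0.5 * (a - c) / denom * df
    lo, hi = max(k - 2, 0), min(k + 3, len(freqs))
    power = float(np.sum(psd[lo:hi]) * df)
    gain = _filter_gain(fps, low_hz, high_hz, order, float(np.clip(f_hat, low_hz, high_hz)))
    amplitude = float(np.sqrt(2.0 * power / max(gain, 0.25)))
    return (float(f_hat), amplitude)


def state_correlation_matrix(states: StateProbSeries) -> pd.DataFrame:
    """Pairwise Pearson correlations between the 7 state probability traces.

    Entries involving a constant trace are missing (NaN), not zero — a
    flat classifier output carries no linear association information.  The
    diagonal is fixed at 1.  High off-diagonal values indicate entangled
    movement states (overflow).
    """
    if states.n_frames < 2:
        raise ValueError("need >= 2 frames for correlations")
    df = states.probs
    corr = df.corr()  # pairwise-complete, NaN for zero-variance traces
    np.fill_diagonal(corr.values, 1.0)
    variances = df.var(ddof=0)
    if (variances.fillna(0.0) == 0.0).all():
        warnings.warn("all state traces constant; correlations undefined")
    return corr


def mean_forward_correlation(states: StateProbSeries) -> float:
    """Mean correlation of the six directional traces with face_forward.

    Missing pairwise correlations (constant directional traces) are
    ignored; a constant face_forward trace makes the feature missing.
    """
    corr = state_correlation_matrix(states)
    row = corr.loc["face_forward", [s for s in STATES if s != "face_forward"]]
    if row.isna().all():
        return float("nan")
    return float(row.mean(skipna=True))


def occupancy_times(
    states: StateProbSeries, prob_threshold: float = 0.5
) -> dict[str, float]:
    """Seconds spent in each state.

    A frame is assigned to a state when that state is the argmax across the
    seven traces AND its probability is at least ``prob_threshold`` —
    robust to non-normalised multilabel outputs.  Frames where no state
    reaches the threshold are assigned to none.
    """
    P = states.probs.to_numpy()
    valid = np.isfinite(P).all(axis=1)
    winner = np.argmax(P, axis=1)
    pmax = np.max(P, axis=1)
    assigned = valid & (pmax >= prob_threshold)
    out = {}
    for j, s in enumerate(STATES):
        out[s] = float(np.sum(assigned & (winner == j))) / states.fps
    return out


def symmetry_index(
    states: StateProbSeries, axis: str, prob_threshold: float = 0.5
) -> float:
    """Directional symmetry of one motion axis in [-1, 1].

    (t1 - t2) / (t1 + t2), where t1/t2 are the seconds spent in the axis's
    two opposing states (left / antero direction first, so positive values
    mean more time left or in anterocollis).  0 indicates symmetric
    occupancy; +-1 all time in one direction.  When neither state is ever
    occupied the index is 0 by convention (and a warning is emitted).
    """
    if axis not in AXIS_STATE_PAIRS:
        raise ValueError(
            f"unknown axis {axis!r}; expected one of {sorted(AXIS_STATE_PAIRS)}"
        )
    s1, s2 = AXIS_STATE_PAIRS[axis]
    times = occupancy_times(states, prob_threshold)
    t1, t2 = times[s1], times[s2]
    if t1 + t2 == 0:
        warnings.warn(f"no occupancy on axis {axis!r}; symmetry defined as 0")
        return 0.0
    return (t1 - t2) / (t1 + t2)


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) in nats.

    B counts pairs of length-``m`` templates within Chebyshev distance
    ``r`` (self-matches excluded), A the same for length m+1; both counts
    use the first N-m template start points so the ratio is a conditional
    probability.  Constant series return 0 by convention; B = 0 returns
    NaN (undefined).  ``r`` defaults to 0.15 * SD(series).
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series length {n} too short for m={m} (need >= {m + 2})")
    if np.ptp(x) == 0:
        return 0.0
    if r is None:
        r = 0.15 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive for non-constant series")
    n_templates = n - m
    temp_m = sliding_window_view(x, m)[:n_templates]
    temp_m1 = sliding_window_view(x, m + 1)
    # pdist counts each unordered pair once; matching uses <= r (inclusive)
    b = int(np.count_nonzero(pdist(temp_m, metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(temp_m1, metric="chebyshev") <= r))
    if b == 0:
        return float("nan")
    if a == 0:
        return float("nan")
    return float(-np.log(a / b))


def default_mse_scales(fps: float, max_scale_s: float = 3.0, n_scales: int = 8) -> list[int]:
    """Log-spaced coarse-graining factors from 1 frame up to ``max_scale_s``."""
    max_tau = max(int(round(max_scale_s * fps)), 1)
    taus = np.unique(np.round(np.geomspace(1, max_tau, n_scales)).astype(int))
    return [int(t) for t in taus]


def multiscale_entropy(
    series: np.ndarray,
    fps: float,
    scales: list[int] | None = None,
    m: int = 2,
    r_factor: float = 0.15,
) -> pd.DataFrame:
    """Sample entropy of coarse-grained versions of the series.

    For each scale tau (frames), the series is reduced to the means of
    consecutive non-overlapping windows of tau samples and sample entropy
    is computed with the tolerance r fixed from the ORIGINAL series SD
    (r = r_factor * SD), the standard multiscale-entropy convention.
    Scales leaving fewer than m+2 coarse-grained points are reported
    missing, not fatal.

    Returns a DataFrame with columns tau (frames), scale_s (seconds) and
    entropy (nats).
    """
    x = _clean(series)
    if scales is None:
        scales = default_mse_scales(fps)
    r = r_factor * float(np.std(x))
    rows = []
    for tau in scales:
        if tau < 1:
            raise ValueError("scales must be >= 1 frame")
        n_win = len(x) // tau
        if n_win < m + 2:
            rows.append({"tau": tau, "scale_s": tau / fps, "entropy": np.nan})
            continue
        coarse = x[: n_win * tau].reshape(n_win, tau).mean(axis=1)
        if np.ptp(x) == 0:
            ent = 0.0
        else:
            ent = sample_entropy(coarse, m=m, r=r)
        rows.append({"tau": tau, "scale_s": tau / fps, "entropy": ent})
    return pd.DataFrame(rows)


def distance_correlation(
    x: np.ndarray, y: np.ndarray, unbiased: bool = False
) -> float:
    """Distance correlation between two (possibly multivariate) samples.

    With ``unbiased=False`` the classical V-statistic estimator: Euclidean
    distance matrices are double-centred and dCor = sqrt(dCov2 /
    sqrt(dVarX * dVarY)); 0 iff independence in the population limit, 1
    for identical samples.  With ``unbiased=True`` the bias-corrected
    U-statistic estimator (U-centred distance matrices), whose dCov2 has
    expectation 0 under independence even at modest effective sample
    sizes; negative corrected values are clipped to 0.
    """
    X = np.asarray(x, dtype=float)
    Y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(X) != len(Y):
        raise ValueError("samples must have equal length")
    n = len(X)
    if n < (4 if unbiased else 2):
        raise ValueError("too few observations for this estimator")
    a = cdist(X, X)
    b = cdist(Y, Y)
    if unbiased:
        a = _u_center(a)
        b = _u_center(b)
        norm = n * (n - 3)
        dcov2 = float((a * b).sum()) / norm
        dvarx = float((a * a).sum()) / norm
        dvary = float((b * b).sum()) / norm
    else:
        a = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
        b = b - b.mean(axis=0) - b.mean(axis=1)[:, None] + b.mean()
        dcov2 = float((a * b).mean())
        dvarx = float((a * a).mean())
        dvary = float((b * b).mean())
    denom = np.sqrt(dvarx * dvary) if dvarx > 0 and dvary > 0 else 0.0
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def _u_center(d: np.ndarray) -> np.ndarray:
    """U-centred distance matrix (zero diagonal, unbiased centring)."""
    n = len(d)
    row = d.sum(axis=1, keepdims=True)
    col = d.sum(axis=0, keepdims=True)
    total = d.sum()
    out = d - row / (n - 2) - col / (n - 2) + total / ((n - 1) * (n - 2))
    np.fill_diagonal(out, 0.0)
    return out


def _narrowband_phase(
    x: np.ndarray, fps: float, f_center: float, half_width: float, order: int = 4
) -> np.ndarray:
    """Instantaneous phase of the analytic signal in a narrow band."""
    lo = max(f_center - half_width, 1e-3)
    hi = min(f_center + half_width, fps / 2 * 0.999)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fps, output="sos")
    nb = sps.sosfiltfilt(sos, x)
    return np.angle(sps.hilbert(nb))


def harmonic_strength(
    series: np.ndarray,
    fps: float,
    f0: float | None = None,
    max_n: int = 3000,
) -> float:
    """Phase coupling between the dominant tremor frequency and 2*f0.

    The trace is narrow-band filtered around the fundamental f0 and its
    first harmonic 2*f0 (half-width max(0.5 Hz, 0.1*f0)); instantaneous
    phases come from the analytic (Hilbert) signal.  The fundamental phase
    is doubled (a 1:2 locked harmonic satisfies phi2 = 2*phi1 + const) and
    both phases are embedded on the unit circle as (cos phi, sin phi) to
    respect circularity; perfect locking then relates the two embeddings
    by a rigid rotation, so the returned distance correlation is 1 for a
    phase-locked harmonic and near 0 for independent narrowband
    components.

    Missing (NaN) when no dominant frequency exists or 2*f0 reaches the
    Nyquist frequency.  For long recordings the phase series are evenly
    subsampled to at most ``max_n`` points before the O(n^2) distance
    correlation.
    """
    x = _clean(series)
    if f0 is None:
        f0, _amp = dominant_oscillation(x, fps)
    if not np.isfinite(f0):
        return float("nan")
    half_width = max(0.5, 0.1 * f0)
    if 2 * f0 + half_width >= fps / 2:
        warnings.warn(
            f"first harmonic of f0={f0:.2f} Hz exceeds Nyquist ({fps / 2} Hz); "
            "harmonic strength undefined"
        )
        return float("nan")
    phi1 = _narrowband_phase(x, fps, f0, half_width)
    phi2 = _narrowband_phase(x, fps, 2 * f0, half_width)
    if len(phi1) > max_n:
        step = int(np.ceil(len(phi1) / max_n))
        phi1, phi2 = phi1[::step], phi2[::step]
    e1 = np.column_stack([np.cos(2 * phi1), np.sin(2 * phi1)])
    e2 = np.column_stack([np.cos(phi2), np.sin(phi2)])
    return distance_correlation(e1, e2, unbiased=True)


def _resample_states(states: StateProbSeries, fps: float, n_frames: int) -> StateProbSeries:
    """Linear resampling of state traces onto an angle-series frame grid."""
    t_src = np.arange(states.n_frames) / states.fps
    t_dst = np.arange(n_frames) / fps
    cols = {}
    for s in STATES:
        cols[s] = np.interp(t_dst, t_src, states.trace(s))
    return StateProbSeries(fps=fps, probs=pd.DataFrame(cols))


def extract_features(
    angles: HeadAngleSeries,
    states: StateProbSeries | None = None,
    segments: SegmentAnnotation | None = None,
    low_hz: float = 2.0,
    high_hz: float = 10.0,
    filter_order: int = 6,
    prob_threshold: float = 0.5,
    mse_scales: list[int] | None = None,
    recording_id: str | None = None,
) -> pd.DataFrame:
    """Assemble the full feature vector for one recording as a tidy table.

    Angle-derived features (oscillations, multiscale entropy, harmonic
    strength) are always attempted; state-derived features (correlations,
    symmetries) require ``states``; static deviations require a
    ``null_position`` segment annotation — the generalised-dystonia setting
    where such annotations are unavailable simply yields those features as
    missing with a recorded reason.

    Returns a DataFrame with columns feature, value, unit, missing_reason
    (plus recording_id when given).
    """
    entries: list[tuple[str, float | None, str, str | None]] = []

    for ax in AXES:
        x = angles.axis(ax)
        try:
            f_hat, amp = dominant_oscillation(
                x, angles.fps, low_hz=low_hz, high_hz=high_hz, order=filter_order
            )
        except ValueError as exc:
            entries.append((f"osc_freq_{ax}", None, "Hz", str(exc)))
            entries.append((f"osc_amp_{ax}", None, "deg", str(exc)))
            entries.append((f"harmonic_strength_{ax}", None, "unitless", str(exc)))
        else:
            if np.isnan(f_hat):
                entries.append(
                    (f"osc_freq_{ax}", None, "Hz", "no in-band peak above detectability floor")
                )
                entries.append((f"osc_amp_{ax}", 0.0, "deg", None))
                entries.append(
                    (f"harmonic_strength_{ax}", None, "unitless", "no dominant frequency")
                )
            else:
                entries.append((f"osc_freq_{ax}", f_hat, "Hz", None))
                entries.append((f"osc_amp_{ax}", amp, "deg", None))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hs = harmonic_strength(x, angles.fps, f0=f_hat)
                if np.isnan(hs):
                    entries.append(
                        (f"harmonic_strength_{ax}", None, "unitless", "harmonic above Nyquist")
                    )
                else:
                    entries.append((f"harmonic_strength_{ax}", hs, "unitless", None))
        try:
            mse = multiscale_entropy(x, angles.fps, scales=mse_scales)
        except ValueError as exc:
            entries.append((f"mse_{ax}", None, "nats", str(exc)))
        else:
            for _, row in mse.iterrows():
                name = f"mse_{ax}_{row['scale_s']:.3f}s"
                if np.isnan(row["entropy"]):
                    entries.append((name, None, "nats", "too few coarse-grained points"))
                else:
                    entries.append((name, row["entropy"], "nats", None))

    if states is not None:
        if abs(states.fps - angles.fps) > 1e-9 or states.n_frames != angles.n_frames:
            states = _resample_states(states, angles.fps, angles.n_frames)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr = state_correlation_matrix(states)
            for i, si in enumerate(STATES):
                for sj in STATES[i + 1 :]:
                    val = corr.loc[si, sj]
                    if np.isnan(val):
                        entries.append(
                            (f"state_corr_{si}__{sj}", None, "unitless", "constant trace")
                        )
                    else:
                        entries.append((f"state_corr_{si}__{sj}", val, "unitless", None))
            mfc = mean_forward_correlation(states)
            if np.isnan(mfc):
                entries.append(
                    ("mean_forward_corr", None, "unitless", "face_forward trace constant")
                )
            else:
                entries.append(("mean_forward_corr", mfc, "unitless", None))
            for axis in AXIS_STATE_PAIRS:
                entries.append(
                    (f"symmetry_{axis}", symmetry_index(states, axis, prob_threshold),
                     "unitless", None)
                )
    else:
        for i, si in enumerate(STATES):
            for sj in STATES[i + 1 :]:
                entries.append((f"state_corr_{si}__{sj}", None, "unitless", "no state traces"))
        entries.append(("mean_forward_corr", None, "unitless", "no state traces"))
        for axis in AXIS_STATE_PAIRS:
            entries.append((f"symmetry_{axis}", None, "unitless", "no state traces"))

    static_reason = None
    static = None
    if segments is None:
        static_reason = "no segment annotations"
    else:
        try:
            static = head_pose.static_deviation(angles, segments)
        except ValueError as exc:
            static_reason = str(exc)
    for ax in AXES:
        if static is not None:
            signed, absolute = static[ax]
            entries.append((f"static_signed_{ax}", signed, "deg", None))
            entries.append((f"static_abs_{ax}", absolute, "deg", None))
        else:
            entries.append((f"static_signed_{ax}", None, "deg", static_reason))
            entries.append((f"static_abs_{ax}", None, "deg", static_reason))

    return feature_table(entries, recording_id=recording_id)
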