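"""Kinematic features: filters, spectra, correlations, entropy, harmonics.

Sample entropy and distance correlation are checked against brute-force
loop oracles written directly from the definitions, plus an independent
library implementation for the 1-D distance correlation.
"""

import numpy as np
import pandas as pd
import pytest

from dyskin import features as kf
from dyskin import synthetic
from dyskin.types import AXES, STATES, HeadAngleSeries, Segment, SegmentAnnotation
from conftest import make_states


# ---------------------------------------------------------------- oracles
def sampen_bruteforce(x, m, r):
    """O(N^2) template counting straight from the definition."""
    n = len(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0 or a == 0:
        return np.nan, a, b
    return -np.log(a / b), a, b


def dcor_bruteforce(X, Y):
    """Naive double-loop V-statistic distance correlation."""
    X = np.atleast_2d(np.asarray(X, float).T).T
    Y = np.atleast_2d(np.asarray(Y, float).T).T
    n = len(X)
    a = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    b = np.array([[np.linalg.norm(Y[i] - Y[j]) for j in range(n)] for i in range(n)])
    A = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    B = b - b.mean(0) - b.mean(1)[:, None] + b.mean()
    dcov2 = (A * B).mean()
    return np.sqrt(max(dcov2, 0) / np.sqrt((A * A).mean() * (B * B).mean()))


# ---------------------------------------------------------------- bandpass
class TestBandpass:
    def test_in_band_tone_amplitude_preserved(self):
        fps, t = 30.0, np.arange(1800) / 30.0
        x = np.sin(2 * np.pi * 4 * t)
        y = kf.bandpass(x, fps)
        mid = slice(200, -200)  # avoid edge transients
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_tone_rejected(self):
        fps, t = 30.0, np.arange(1800) / 30.0
        x = np.sin(2 * np.pi * 0.5 * t)
        y = kf.bandpass(x, fps)
        assert np.abs(y[200:-200]).max() < 0.05

    def test_constant_series_zeroed(self):
        y = kf.bandpass(np.full(500, 7.0), 30.0)
        assert np.allclose(y, 0.0, atol=1e-8)

    def test_low_fps_and_short_series_errors(self):
        with pytest.raises(ValueError, match="Nyquist"):
            kf.bandpass(np.zeros(500), fps=20.0)
        with pytest.raises(ValueError, match="too short"):
            kf.bandpass(np.zeros(10), fps=30.0)


# ------------------------------------------------------ dominant oscillation
class TestDominantOscillation:
    def test_pure_tone_with_offset_recovered(self):
        fps, t = 30.0, np.arange(1800) / 30.0
        x = 20.0 + 5.0 * np.sin(2 * np.pi * 4 * t)
        f, a = kf.dominant_oscillation(x, fps)
        assert f == pytest.approx(4.0, abs=0.2)
        assert a == pytest.approx(5.0, rel=0.15)

    def test_frequency_invariant_to_offset_and_drift(self):
        fps, t = 30.0, np.arange(1800) / 30.0
        base = 5.0 * np.sin(2 * np.pi * 4 * t)
        f0, _ = kf.dominant_oscillation(base, fps)
        f1, _ = kf.dominant_oscillation(base + 30.0 + 10 * np.sin(2 * np.pi * 0.2 * t), fps)
        assert f1 == pytest.approx(f0, abs=0.05)

    def test_white_noise_mostly_undetected(self):
        detected = 0
        for seed in range(60):
            x = np.random.default_rng(seed).standard_normal(1800)
            f, a = kf.dominant_oscillation(x, 30.0)
            detected += int(np.isfinite(f))
        assert detected <= 6  # detectability floor suppresses flat spectra

    def test_constant_series(self):
        f, a = kf.dominant_oscillation(np.full(600, 3.0), 30.0)
        assert np.isnan(f) and a == 0.0

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="window"):
            kf.dominant_oscillation(np.zeros(30), 30.0)


# ----------------------------------------------------------- state features
class TestStateCorrelations:
    def test_self_and_anti_correlation(self, rng):
        x = rng.uniform(0, 1, 500)
        states = make_states(
            face_forward=x, rotation_left=x, rotation_right=1 - x,
            tilt_left=rng.uniform(0, 1, 500),
        )
        corr = kf.state_correlation_matrix(states)
        assert corr.loc["face_forward", "rotation_left"] == pytest.approx(1.0)
        assert corr.loc["rotation_left", "rotation_right"] == pytest.approx(-1.0)
        assert (np.diag(corr) == 1.0).all()

    def test_independent_traces_near_zero(self, rng):
        traces = {s: rng.uniform(0, 1, 10**4) for s in STATES}
        corr = kf.state_correlation_matrix(make_states(**traces))
        off = corr.to_numpy()[~np.eye(7, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_constant_trace_missing_not_zero(self, rng):
        states = make_states(
            face_forward=rng.uniform(0, 1, 100), rotation_left=np.full(100, 0.5)
        )
        corr = kf.state_correlation_matrix(states)
        assert np.isnan(corr.loc["face_forward", "rotation_left"])

    def test_affine_rescaling_invariance(self, rng):
        x = rng.uniform(0, 1, 300)
        y = rng.uniform(0, 1, 300)
        c1 = kf.state_correlation_matrix(make_states(face_forward=x, tilt_left=y))
        c2 = kf.state_correlation_matrix(
            make_states(face_forward=0.2 + 0.5 * x, tilt_left=y)
        )
        assert c1.loc["face_forward", "tilt_left"] == pytest.approx(
            c2.loc["face_forward", "tilt_left"]
        )


class TestMeanForwardCorrelation:
    def test_complementary_traces_give_minus_one(self, rng):
        ff = rng.uniform(0, 1, 400)
        states = make_states(**{"face_forward": ff, **{s: 1 - ff for s in STATES[1:]}})
        assert kf.mean_forward_correlation(states) == pytest.approx(-1.0)

    def test_constructed_mixture_averages_to_zero(self, rng):
        n = 20000
        ff = rng.standard_normal(n)
        noise = rng.standard_normal((6, n))
        # three traces at r ~ +0.5, three at r ~ -0.5
        pos = 0.5 + 0.1 * (ff + np.sqrt(3) * noise[:3]) / 4
        neg = 0.5 + 0.1 * (-ff + np.sqrt(3) * noise[3:]) / 4
        traces = dict(zip(STATES[1:4], pos))
        traces.update(dict(zip(STATES[4:], neg)))
        states = make_states(face_forward=0.5 + 0.1 * ff / 4, **traces)
        assert kf.mean_forward_correlation(states) == pytest.approx(0.0, abs=0.02)

    def test_constant_forward_trace_missing(self, rng):
        states = make_states(
            face_forward=np.full(100, 0.9), rotation_left=rng.uniform(0, 1, 100)
        )
        assert np.isnan(kf.mean_forward_correlation(states))


class TestSymmetryIndex:
    def test_worked_example_seven_vs_three_seconds(self):
        fps = 10.0
        left = np.r_[np.ones(70), np.zeros(30)] * 0.9
        right = np.r_[np.zeros(70), np.ones(30)] * 0.9
        states = make_states(fps=fps, rotation_left=left, rotation_right=right)
        assert kf.symmetry_index(states, "rotation") == pytest.approx(0.4)

    def test_equal_occupancy_zero(self):
        left = np.r_[np.ones(50), np.zeros(50)] * 0.8
        states = make_states(rotation_left=left, rotation_right=left[::-1])
        assert kf.symmetry_index(states, "rotation") == 0.0

    def test_one_sided_extremes(self):
        states = make_states(tilt_left=np.full(40, 0.95))
        assert kf.symmetry_index(states, "tilt") == 1.0
        states = make_states(tilt_right=np.full(40, 0.95))
        assert kf.symmetry_index(states, "tilt") == -1.0

    def test_antisymmetric_under_state_swap(self, rng):
        # continuous traces: exact argmax ties have probability zero
        a = rng.uniform(0, 1, 300)
        b = rng.uniform(0, 1, 300) ** 2
        s1 = make_states(anterocollis=a, retrocollis=b)
        s2 = make_states(anterocollis=b, retrocollis=a)
        assert kf.symmetry_index(s1, "pitch") == pytest.approx(
            -kf.symmetry_index(s2, "pitch")
        )

    def test_no_occupancy_flagged_zero(self):
        states = make_states(face_forward=np.full(50, 0.9))
        with pytest.warns(UserWarning, match="no occupancy"):
            assert kf.symmetry_index(states, "rotation") == 0.0

    def test_unknown_axis_error(self):
        with pytest.raises(ValueError, match="unknown axis"):
            kf.symmetry_index(make_states(face_forward=np.ones(10)), "shear")

    def test_sub_threshold_probability_not_counted(self):
        # argmax alone is not enough: probability must reach 0.5
        states = make_states(rotation_left=np.full(60, 0.4))
        with pytest.warns(UserWarning):
            assert kf.symmetry_index(states, "rotation") == 0.0


# ----------------------------------------------------------------- entropy
class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert kf.sample_entropy(np.full(100, 2.0)) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        x = rng.standard_normal(n)
        r = 0.2 * np.std(x)
        expected, a, b = sampen_bruteforce(x, 2, r)
        got = kf.sample_entropy(x, m=2, r=r)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected  # exact: identical counts

    def test_alternating_series_matches_oracle(self):
        x = np.array([1.0, 0.0] * 40)
        r = 0.2 * np.std(x)
        expected, _, _ = sampen_bruteforce(x, 2, r)
        got = kf.sample_entropy(x, m=2, r=r)
        assert got == expected
        assert np.isfinite(got)

    def test_noise_more_entropic_than_sine(self):
        rng = np.random.default_rng(0)
        t = np.arange(3000) / 30
        sine = np.sqrt(2) * np.sin(2 * np.pi * 1.0 * t)
        noise = rng.standard_normal(3000)
        r = 0.15  # same tolerance, equal-variance series
        assert kf.sample_entropy(noise, r=r) > kf.sample_entropy(sine, r=r)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            kf.sample_entropy(np.zeros(3), m=2)


class TestMultiscaleEntropy:
    def test_coarse_grain_lengths_and_tau1_identity(self, rng):
        x = rng.standard_normal(1000)
        out = kf.multiscale_entropy(x, fps=30.0, scales=[1, 3, 7, 50])
        assert list(out["tau"]) == [1, 3, 7, 50]
        # tau=1 equals plain sample entropy at the same tolerance
        r = 0.15 * np.std(x)
        assert out.loc[0, "entropy"] == kf.sample_entropy(x, r=r)
        assert np.allclose(out["scale_s"], np.array([1, 3, 7, 50]) / 30.0)

    def test_white_noise_entropy_nonincreasing_in_scale(self):
        # median over seeds: coarse-graining averages away variance
        firsts, lasts = [], []
        for seed in range(30):
            x = np.random.default_rng(seed).standard_normal(3000)
            out = kf.multiscale_entropy(x, fps=30.0, scales=[1, 2, 5, 10])
            firsts.append(out["entropy"].iloc[0])
            lasts.append(out["entropy"].iloc[-1])
        assert np.median(firsts) > np.median(lasts)

    def test_scale_with_too_few_points_missing_not_fatal(self, rng):
        x = rng.standard_normal(50)
        out = kf.multiscale_entropy(x, fps=30.0, scales=[1, 25])
        assert np.isfinite(out["entropy"].iloc[0])
        assert np.isnan(out["entropy"].iloc[1])


# --------------------------------------------------- distance correlation
class TestDistanceCorrelation:
    def test_identity_is_one(self, rng):
        x = rng.standard_normal(100)
        assert kf.distance_correlation(x, x) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_multivariate(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 2))
        Y = X * 0.5 + rng.standard_normal((60, 2))
        assert kf.distance_correlation(X, Y) == pytest.approx(
            dcor_bruteforce(X, Y), abs=1e-12
        )

    def test_matches_pingouin_univariate(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.standard_normal(80)
        y = 0.3 * x + rng.standard_normal(80)
        ref = pingouin.distance_corr(x, y, n_boot=None)
        assert kf.distance_correlation(x, y) == pytest.approx(float(ref), abs=1e-10)

    def test_unbiased_near_zero_under_independence(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        assert kf.distance_correlation(x, y, unbiased=True) < 0.15


class TestHarmonicStrength:
    def test_phase_locked_construction_strong(self):
        fps, t = 30.0, np.arange(60 * 30) / 30.0
        x = np.sin(2 * np.pi * 4 * t) + 0.5 * np.sin(4 * np.pi * 4 * t)
        assert kf.harmonic_strength(x, fps, f0=4.0) > 0.9

    def test_amplitude_scaling_invariance(self):
        fps, t = 30.0, np.arange(60 * 30) / 30.0
        x = np.sin(2 * np.pi * 4 * t) + 0.5 * np.sin(4 * np.pi * 4 * t)
        a = kf.harmonic_strength(x, fps, f0=4.0)
        b = kf.harmonic_strength(10 * x, fps, f0=4.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_locked_stronger_than_unlocked_generator(self):
        def strength(locked, seed):
            spec = synthetic.MotionSpec(
                duration_s=120, fps=30,
                tremor={"yaw": synthetic.TremorSpec(4, 5, 0.5, locked)},
                angle_noise_sd=0.5, seed=seed,
            )
            a, _ = synthetic.simulate_angle_series(spec)
            return kf.harmonic_strength(a.yaw, 30, f0=4.0)

        locked = [strength(True, s) for s in range(3)]
        unlocked = [strength(False, s) for s in range(3)]
        assert min(locked) > 0.9
        assert max(unlocked) < min(locked)

    def test_no_dominant_frequency_missing(self):
        assert np.isnan(kf.harmonic_strength(np.full(600, 1.0), 30.0))

    def test_harmonic_above_nyquist_flagged_missing(self):
        fps, t = 30.0, np.arange(1800) / 30.0
        x = np.sin(2 * np.pi * 8 * t)
        with pytest.warns(UserWarning, match="Nyquist"):
            assert np.isnan(kf.harmonic_strength(x, fps, f0=8.0))


# ------------------------------------------------------------ full vector
class TestExtractFeatures:
    def _recording(self, seed=0):
        spec = synthetic.MotionSpec(
            duration_s=40, fps=30,
            tonic_deviation={"yaw": 18.0, "tilt": -6.0},
            tremor={"yaw": synthetic.TremorSpec(5.0, 4.0, harmonic_ratio=0.5)},
            drift_amplitude=1.0, angle_noise_sd=0.3, seed=seed,
        )
        angles, truth = synthetic.simulate_angle_series(spec)
        states = synthetic.simulate_state_probs(angles, noise_sd=0.01, seed=seed)
        segments = SegmentAnnotation([Segment("null_position", 0, 300)])
        return angles, states, segments, truth

    def test_planted_parameters_recovered(self):
        angles, states, segments, truth = self._recording()
        table = kf.extract_features(angles, states, segments, recording_id="rec1")
        vals = table.set_index("feature")["value"]
        assert vals["osc_freq_yaw"] == pytest.approx(5.0, abs=0.2)
        assert vals["osc_amp_yaw"] == pytest.approx(4.0, rel=0.15)
        assert vals["harmonic_strength_yaw"] > 0.9
        assert vals["static_signed_yaw"] == pytest.approx(18.0, abs=1.0)
        assert vals["static_abs_tilt"] == pytest.approx(6.0, abs=1.0)
        # sustained left rotation => strong leftward asymmetry
        assert vals["symmetry_rotation"] > 0.8

    def test_states_absent_gives_angle_only_vector(self):
        angles, _, segments, _ = self._recording()
        table = kf.extract_features(angles, states=None, segments=segments)
        t = table.set_index("feature")
        assert np.isfinite(t.loc["osc_freq_yaw", "value"])
        assert np.isnan(t.loc["mean_forward_corr", "value"])
        assert t.loc["mean_forward_corr", "missing_reason"] == "no state traces"

    def test_segments_absent_generalised_cohort_mode(self):
        angles, states, _, _ = self._recording()
        table = kf.extract_features(angles, states, segments=None)
        t = table.set_index("feature")
        assert np.isnan(t.loc["static_abs_yaw", "value"])
        assert t.loc["static_abs_yaw", "missing_reason"] == "no segment annotations"
        assert np.isfinite(t.loc["symmetry_rotation", "value"])

    def test_units_recorded(self):
        angles, states, segments, _ = self._recording()
        table = kf.extract_features(angles, states, segments)
        units = table.set_index("feature")["unit"]
        assert units["osc_freq_yaw"] == "Hz"
        assert units["osc_amp_pitch"] == "deg"
        assert units["static_abs_yaw"] == "deg"
        assert all(units[u] == "nats" for u in units.index if u.startswith("mse_"))
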