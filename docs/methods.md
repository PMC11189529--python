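# Methods

This note documents the models and procedures implemented in `dyskin`,
the parameter choices that matter, what the synthetic generators do and
do not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Head-pose model

Landmarks are treated as a rigid body: frame `t` observations are modelled
as `X_t = R_t T + c_t + ε`, with `T` a face-forward template (centred,
at least 4 non-coplanar points), `R_t` a proper rotation, `c_t` a
translation removed by centring both point sets, and `ε` isotropic noise.
`R_t` is the orthogonal Procrustes solution via SVD of the
cross-covariance, with the smallest singular vector sign-flipped when the
unconstrained optimum is a reflection. Scale is deliberately not fitted:
monocular face-mesh scale is arbitrary, so templates use dimensionless
rigid-body units and noise is quoted relative to the template RMS radius.

**Euler convention (fixed package-wide).** Right-handed camera-fixed
axes: x to the subject's anatomical left, y superior, z anterior.
Intrinsic rotations applied yaw (about y), then pitch (about x), then
tilt/roll (about z). Signs: yaw > 0 rotates the nose toward the subject's
left; pitch > 0 is flexion (anterocollis); tilt > 0 brings the left ear
toward the left shoulder. Nothing downstream depends on the specific
convention — the analyses use magnitudes and within-convention contrasts —
but it is enforced by tests (sign probes on landmark images and
compose/decompose round trips to 1e-9). Decompositions with |pitch|
within 0.5° of ±90° are flagged gimbal-degenerate.

**Missing frames** propagate as NaN angles; interior gaps ≤ 0.5 s are
linearly interpolated, longer gaps stay missing. This is an artifact
policy (clinical pipelines typically exclude poor-quality video
entirely); it keeps synthetic dropouts from silently shifting spectra.

**Static deviation** per axis is the median angle over all annotated
null-position frames (≥ 1 s required). The median rather than the mean is
used because tremor excursions ride on the tonic posture; the aggregator
is a package choice. Absolute deviations feed the dominant-axis phenotype
label, with deterministic tie-break yaw > tilt > pitch.

## Kinematic features

**Band-pass.** Zero-phase (forward–backward) Butterworth, order 6,
2–10 Hz by default, applied as second-order sections for numerical
stability. The band isolates dystonic jerks/tremor from intended slow
movements, patient sway and camera motion (< 2 Hz) and tracking jitter
(> 10 Hz). When slow artifacts are absent a 1 Hz low cut is available
(`low_hz=1`); 2 Hz is the default used throughout. Sampling rates at or
below 20 fps cannot resolve the 10 Hz band edge and are rejected with
advice to reduce the band.

**Dominant oscillation.** The band-passed trace is analysed with Welch
averaging of 2 s Hann windows at 50 % overlap (an averaged Fourier
spectrogram). The 2–10 Hz peak must exceed 2× the median in-band power,
otherwise the trace is reported oscillation-free (amplitude 0, frequency
missing): with ~60 windows averaged, white-noise spectra are flat enough
that this floor suppresses false peaks (tested over 60 seeds). The peak
frequency is refined by parabolic interpolation on log-power, giving
sub-bin accuracy (bin width 0.5 Hz at 30 fps). The amplitude is the
sinusoid-equivalent amplitude of the power integrated over the peak ± 2
bins (the Hann main lobe), divided by the squared filter gain at the peak
(the filter is applied twice). Summing the main lobe rather than taking
the single peak bin is what makes the estimate accurate: the Hann
window's equivalent noise bandwidth (1.5 bins) and scalloping would
otherwise bias a single-bin amplitude ~18–25 % low. This spectral
definition of amplitude (as opposed to, e.g., an envelope statistic) is a
documented package choice.

**State correlations.** Plain Pearson correlations between the seven
probability traces, pairwise-complete over missing frames. Constant
traces yield missing entries, never 0 — a flat classifier output carries
no association information. No simplex constraint is imposed: the
upstream classifier is multilabel, and the correlations between
co-active states are exactly the signal of interest (overflow).

**Symmetry.** Occupancy assigns a frame to a state when it is the argmax
over the seven traces *and* its probability is ≥ 0.5; this double
condition is robust to non-normalised multilabel outputs. The index is
(t₁ − t₂)/(t₁ + t₂) in seconds, left/antero member first; both-zero
occupancy returns 0 with a warning. Exact argmax ties (measure-zero for
continuous traces) resolve by fixed state order.

**Sample entropy** is −ln(A/B) with B the number of unordered pairs of
length-m templates within Chebyshev distance r (self-matches excluded)
and A the same at length m+1; both counts use the first N−m template
start points so A/B is a conditional probability. Defaults m = 2,
r = 0.15·SD. Constant series return 0 by convention; B = 0 or A = 0 is
undefined (missing). The vectorised implementation is required by tests
to agree *exactly* (identical counts) with an O(N²) brute-force loop.

**Multiscale entropy** coarse-grains by non-overlapping window means
(length ⌊N/τ⌋) with r fixed from the original series SD — the standard
convention, so entropy changes across scales reflect dynamics, not
rescaled tolerances. Default scales: 8 log-spaced values from 1 frame to
3 s, covering the sub-second vs supra-second contrast of interest; scales
leaving fewer than m+2 points are missing, not fatal.

**Harmonic strength.** Narrow-band components at f₀ and 2f₀ (half-width
max(0.5 Hz, 0.1·f₀), order-4 zero-phase Butterworth) give instantaneous
Hilbert phases φ₁, φ₂. The fundamental phase is doubled and both are
embedded on the unit circle, (cos 2φ₁, sin 2φ₁) vs (cos φ₂, sin φ₂);
the statistic is the distance correlation between the two embeddings.
Doubling first matters: under 1:2 locking φ₂ = 2φ₁ + const, so the two
embeddings differ by a rigid rotation and the distance correlation is
exactly 1, whereas embedding φ₁ directly makes perfect locking score
≈ 0.5 (the double-angle map does not preserve distances). The
bias-corrected (U-statistic) distance correlation estimator is used, and
phase series longer than 3000 samples are evenly subsampled before the
O(n²) computation. Missing when no dominant frequency exists or
2f₀ + half-width reaches Nyquist.

## Cohort statistics

Paired contrasts: two-sided Wilcoxon signed-rank with zero differences
discarded (Wilcoxon's original treatment) for both test and effect;
matched-pairs rank-biserial (W⁺ − W⁻)/(W⁺ + W⁻) on |difference| ranks,
positive = larger pre. Unpaired: two-sided Mann–Whitney U with
rank-biserial 2U_a/(n_a·n_b) − 1 (ties half-credited), positive = larger
in group a. Benjamini–Hochberg adjustment is applied across exactly the
features of one contrast call (one "panel"), and features are ranked by
|effect|. Responders are patients with ≥ 30 % relative score improvement
(boundary inclusive); the responder analysis reports the within-subgroup
effect difference, flagging subgroups with < 5 pairs. Sidedness and the
zero-difference policy are package choices where the procedure itself is
underdetermined.

Score prediction uses additive (forward) sequential selection on an OLS
model with internally standardised features, scored by leave-one-out
mean absolute error, stopping when no candidate improves it. LOO was
chosen for determinism at the small cohort sizes typical here (n ≈ 28–40);
no random CV splits means identical results across runs. The candidate
pool can be restricted to static-only or kinematic-only features to
compare feature families.

## Synthetic data: what it emulates, and what it does not

`simulate_angle_series` builds per-axis angle(t) = tonic + drift +
tremor (+ harmonic) + white noise. Drift is white noise low-passed at
0.4 Hz and rescaled — band-limited slow wander that the 2 Hz high-pass
must reject, emulating camera movement or sway. The unlocked-harmonic
mode gives the 2f₀ component an independently diffusing phase; note its
slow diffusion leaves genuine long-range autocorrelation, so
harmonic-strength values on unlocked synthetic tremor are low but not
near-zero — the strict independence null in the tests uses two
independently filtered noise processes instead. `render_landmarks`
applies the per-frame rotation to the template and adds isotropic
Gaussian noise. `simulate_state_probs` soft-thresholds signed angle
exceedance through a logistic (threshold 10°, softness 5° by default) —
the classifier's true response function is unknown, this is a smooth
monotone stand-in — and an optional 7×7 mixing matrix plants inter-state
correlations (synthetic overflow).

`simulate_cohort` draws feature vectors directly at the cohort level:
per-subject baselines N(0,1), planted pre-minus-post shifts expressed in
units of the per-condition noise SD (default 1; the subject baseline
cancels in pairing, so a planted shift s corresponds to a
paired-difference effect size s/√2), between-group offsets, responder
fractions with attenuated shifts in non-responders, and clinical scores
generated as monotone (optionally noisy) functions of a latent severity
on the 0–35 total-score scale with ordinal sub-items.

None of the generators simulate occlusion, tracking dropout structure,
photorealistic appearance, protocol-driven voluntary movements, or
realistic inter-feature correlation structure; passing tests demonstrate
correctness of the *computations* under the stated generative
assumptions, not clinical validity on real video.

## Problem sizes used in tests and the acceptance script

Signal-level checks use 60 s recordings at 30 fps (1800 frames); the
harmonic discrimination checks use 10⁴ frames; geometric round trips use
100-frame trajectories with 20 noise replicates; cohort checks use 40
paired subjects with 20 features and 100–150 null replicates for the
false-discovery estimate; the end-to-end pipeline demo uses 6 subjects ×
2 conditions × 20 s. These sizes give stable Monte-Carlo estimates while
keeping a full run inexpensive.

## Known limitations

- The Euler convention (and therefore all signs) is a documented package
  choice; upstream trackers with their own canonical axes may need an
  adapter that permutes/negates axes before comparison of signed values.
- Rank recovery of a *fine* planted effect-size gradient is limited by
  the sampling noise of rank-biserial estimates: at n = 40 pairs the
  estimate's SD (~0.1–0.18) exceeds the spacing of a 20-step 1.0–0.2 SD
  gradient, so near-perfect rank agreement (Spearman ρ > 0.9) is not a
  statistically achievable expectation at that design size — the
  acceptance suite records this bound as stated and the corresponding
  test documents the shortfall.
- Sample entropy and distance correlation are O(N²); long recordings are
  handled by coarse-graining (MSE) and even subsampling (harmonic
  strength), both documented above.
- The multilabel state simulator is a logistic stand-in, not a model of
  any particular CNN's calibration; state-correlation features on real
  classifier outputs may have different baselines.
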