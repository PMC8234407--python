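# Methods

## Signal model

A trial is 4 s of two-channel data sampled at 250 Hz. The EOG channel is in
μV; the strain channel is the dimensionless relative resistance change
ΔR/R0 of the forehead sensor. Each non-straight trial contains exactly one
event:

* **Horizontal gaze** (left/right): a raised-cosine EOG pulse,
  a·(1 − cos 2πτ/d)/2, amplitude drawn uniformly from 500–600 μV (positive
  for left, negative for right), duration 0.15–0.35 s. A smooth unimodal
  pulse matches the qualitative saccade waveform without committing to an
  unreported shape.
* **Vertical gaze** (up/down): a rise–hold–fall strain plateau of magnitude
  ΔR/R0 = 0.02, duration 1.5–2.2 s with 0.5 s raised-cosine ramps. Vertical
  gaze is a held posture and skin strain follows over a few hundred
  milliseconds, hence the longer, gentler event. Down gaze stretches the
  skin (ΔR > 0) and up gaze compresses it by default; `down_is_stretch`
  flips the convention. The 2 % magnitude is a free choice — no published
  value exists — picked so the conditioned strain event (see below) sits at
  the same order as the EOG spike.

Noise on the EOG channel: a 50 Hz powerline sinusoid (20 μV amplitude,
random phase), white Gaussian noise (15 μV sd), and sinusoidal baseline
drift (30 μV, period ≥ trial length). The strain channel receives the same
recipe scaled by `strain_noise_scale = 1/strain_to_uv`, i.e. equal
equivalent magnitude once conditioned. The `rigid` electrode mode multiplies
the powerline and white-noise amplitudes by 2 (default): the degradation of
a rigid electrode is poorer skin contact, not a different mechanism; drift
is treated as a skin property common to both modes.

All randomness flows through `numpy` Generators seeded per trial from a
master seed, so datasets are bit-reproducible.

## Compound signal and front end

The sensor physically delivers one waveform in which the strain signal is
superimposed on the EOG. The pipeline therefore forms
`compound = eog + strain_to_uv · strain_rel` with
`strain_to_uv = 25000 μV` per unit ΔR/R0 (a 0.02 event ≈ 500 μV, matching
the observed prominence of both event types in one trace).

Front-end emulation: ideal gain (default 1000, placing a 600 μV spike at
~36 % of the ±1.65 V ADC range), a second-order IIR notch with 48–52 Hz
−3 dB band, and a 4th-order Butterworth low-pass. Both filters run
forward–backward for zero phase so event timing is not skewed; the
Butterworth design cutoff is pre-warped by (√2−1)^(−1/8) so the *two-pass*
response is −3 dB at the configured 10 Hz. The 12-bit mid-rise ADC clips
out-of-range samples and reconstructs in-range samples within half an LSB
(~0.4 mV at the ADC, ~0.4 μV input-referred).

## Kalman smoothing

A scalar random-walk observation model (A = 1, B = 0, C = 1) with Q = 1 μV²
and R = 225 μV² (the square of the default white-noise sd). The steady-state
gain ≈ 0.065 gives a ~60 ms smoothing constant: strong suppression of
residual broadband noise at the cost of ~20 % peak attenuation on the
fastest saccades — acceptable because detection thresholds sit at half the
minimum spike amplitude. x₀ defaults to the first sample and P₀ to R to
avoid a start-up transient. Joint scaling of (Q, R, P₀) leaves the output
invariant; only their ratio matters.

## Wavelet separation

Decomposition uses the orthogonal Daubechies-4 family, 6 levels at 250 Hz
(approximation band 0–2 Hz), symmetric boundary extension. The strain
component is the reconstruction from the coarse branches (approximation
orders ≥ `split_level`, default the coarsest only); the EOG component is
the remainder, so the two always sum to the input exactly. Detail
coefficients are denoised with the universal threshold σ̂·√(2 ln L), σ̂ from
the median absolute deviation of the level-1 details, soft shrinkage by
default; the sub-threshold residue is folded into the EOG component to
preserve additivity.

A plain level split is not sufficient: a 0.15–0.35 s unipolar saccade pulse
carries roughly a third of its energy below 1 Hz, which a time-local
approximation branch absorbs, bleeding several hundred μV into the strain
estimate. Before the final split, an **event-masking pass** removes this
leakage: excursions of the residue against a one-level-deeper approximation
exceeding `mask_threshold` (150 μV, ~level of a saccade residue and well
above plateau-edge and noise residues) are dilated by 0.15 s and bridged by
linear interpolation, and the approximation is re-estimated (2 iterations).
Sub-threshold structure — the strain plateau, drift, noise — is never
masked. On generator-scale mixtures the recovered components correlate with
their ground-truth ingredients at ≥ 0.93 (worst case over random
placements), with zero cross-channel event leakage at the detection
thresholds.

## Events and features

An event is a maximal run with |x| above threshold lasting ≥ 0.05 s.
Thresholds: 250 μV for the EOG component (half the minimum spike) and
ΔR/R0 = 0.01 for the strain component (half the event magnitude). Each
trial yields the 8-vector ζ — per channel: signed peak amplitude of the
largest event, its duration, its gap to the previous event (0 for the
first; "interval" is read as gap-to-previous, not latency from trial
start), and the event count. Features are z-scored with training-set
statistics: a single Gaussian-kernel width cannot otherwise serve
coordinates in μV, seconds and counts at once.

## Classifier and decision rule

C(5,2) = 10 binary soft-margin SVMs (penalty C = 1) are trained one per
state pair on the z-scored features; the Gram matrix comes from the
package's own Gaussian kernel, with σ defaulting to the median pairwise
training distance. The quadratic programs are solved by scikit-learn's SMO
(`kernel="precomputed"`); support vectors, dual weights and biases are
extracted so a trained model is a plain JSON document.

Votes aggregate to V = Σ_k w_k·m_k with midpoints m: up +0.5, down −0.5,
left +1.5, right −1.5, straight 0, where w_k is the vote share over the
four contests involving the plurality winner (ties average the tied
classes' scores). Restricting to the winner's contests is deliberate: for a
feature vector far from both classes of an unrelated pair, the RBF
similarities vanish and that pair's vote degenerates to the sign of its
bias — noise that a global weighted sum lets cancel the true midpoint. A
unanimous sweep lands V exactly on the winner's midpoint; V is decoded by
the open intervals up (0,1), down (−1,0), left (1,2), right (−2,−1), and
any V within ε = 0.05 of a boundary — including 0 — reads as straight.
Trials with no detected event on either channel short-circuit to straight.

## Evaluation

The confusion matrix keeps the reversed-row convention (columns = actual in
order straight, up, down, left, right; rows = recognized in the reverse
order), so correct counts lie on the anti-diagonal and
Sₙ = a₍₆₋ₙ₎ₙ / Σᵢ aᵢₙ; overall accuracy is the unweighted mean. A
conventional diagonal matrix is exported alongside. The benchmark protocol
generates 600 balanced trials (120 per state), splits them 50/50 stratified
(the source protocol states only that the data were split; pooled
splitting is used), trains on one half and scores the other, and averages
over ten master seeds. One condition completes in ~15 s on a single CPU.

## What the generator does and does not show

The generator reproduces the *signal-level* structure: amplitudes,
timescales, channel assignment, powerline/white/drift interference, and a
contact-noise-doubled rigid mode. It does not model blinks, head-motion
artifacts, inter-subject amplitude variability, electrode impedance drift,
or gaze held across trial boundaries — the factors that dominate errors in
real recordings. Benchmark accuracies on synthetic data (≈ 99.7 % clean,
marginally lower in rigid mode) therefore demonstrate correctness of the
chain at the stated noise levels, not expected field performance; the
rigid-mode degradation in particular is mild because doubled powerline and
white noise are almost entirely removed by the notch/low-pass/Kalman
stages.

## Numerical choices and degenerate inputs

* Filters reject bands/cutoffs outside the Nyquist range; traces must match
  the configured sampling rate.
* Zero-variance feature coordinates pass through z-scoring unscaled.
* A singular innovation covariance, an empty series, an unknown gaze state,
  an unfitted normalizer, or a class missing from a training split raise
  named errors rather than propagating NaNs.
* The plate-pressure formula exposes its π exponent as a constant
  (`PLATE_PI_EXPONENT = 4`, the plate-theory series term); the resistivity
  formula returns both ρ and 1/ρ explicitly since data sheets often label
  one as the other.
* Event detection quantizes durations/intervals to the sample grid; tests
  allow one sample period of slack.

## Known limitations

* The separation masking assumes saccade-scale events exceed 150 μV in the
  compound signal; much weaker spikes would pass into the strain branch.
* The interval decision rule is only as informative as the vote pattern;
  V does not carry calibrated confidence.
* Streaming operation (dwell-filtered command latching, default 0.5 s) is
  provided as a utility but the per-trial protocol is the primary,
  benchmarked contract.
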