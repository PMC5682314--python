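# Methods

This note documents the models, parameter choices and numerical decisions
behind `mmgtap`, and states precisely what the synthetic experiments do and
do not establish.

## Signal model and preprocessing

An MMG recording is a uniformly sampled multi-channel acceleration series
(default 1 kHz, two channels on the extensor digitorum). Muscle vibration
during a finger tap concentrates below 50 Hz with the dominant band around
10–22 Hz; everything else is treated as noise or artifact.

Preprocessing is a 4th-order Butterworth band-pass, 0.1–50 Hz. The default
application is forward–backward (`sosfiltfilt`), which is zero-phase —
event boundaries are not skewed by group delay — at the cost of squaring
the magnitude response (the analytic response used by the tests accounts
for this). A causal single-pass mode exists for streaming parity.

Two numerical points matter at the 0.1 Hz edge:

* the slowest pole settles over τ ≈ fs/(2π·0.1) ≈ 1.6 s, so scipy's default
  padding (tens of samples) leaves multi-second edge transients. We pad by
  3τ with **even** extension; odd extension around a non-zero endpoint
  injects a large low-frequency step response at the trailing edge.
* even with correct padding, the mirror image of a strong burst close to a
  recording edge leaks slow-pole energy back into the signal. Detection
  therefore ignores activation within an `edge_guard` (default 2 s) of the
  recording edges, and the simulator ends recordings 5 s after the last tap.

## Tapping-event detection

Both detectors share the same calibration idea: a threshold equal to a
scaling factor α times the mean of an activity measure over a known rest
interval (`T_s1`, `T_s2`).

**RMS detector.** Sliding-window RMS with `W` = 400 ms (the upper end of
the 100–400 ms analysis-window range customary for MMG), α = 2.15. The
envelope value at index `t` summarises the forward window `x[t:t+W)`;
reported event times are recentred by `W/2` so timestamps refer to the
window centre (`recenter=False` restores the literal forward-window
convention, which skews onsets up to 400 ms early at high SNR).

**DTF detector.** Convolution with the 17-tap antisymmetric difference
template (eight −1s, a zero, eight +1s), 'same'-aligned on the zero tap,
rectified, α = 2. Rectification alone is not sufficient on a stochastic
baseline: the threshold 2×mean(|response|) sits at ≈1.6σ of a near-Gaussian
process, which is exceeded on ~11% of rest samples in dense short runs —
no run-level post-processing can separate taps from that. The rectified
response is therefore smoothed with a 200 ms centred moving average before
thresholding. Smoothing does not change the threshold definition (the mean
of a moving average is the mean); it turns the response into an activity
envelope, exactly the role the threshold rule assumes. `smooth=0` gives
the literal response.

**Segmentation.** `Z[t] = 1` iff the activity measure exceeds the
threshold; per-channel activations are OR-combined (a tap must be visible
on at least one sensor). Runs separated by less than `merge_gap` (200 ms)
are merged, runs shorter than `min_event_duration` (100 ms) are dropped.
At 30 taps/min the 200 ms merge cannot fuse neighbouring taps.

**Boundary refinement.** The 400 ms RMS window dilates detected runs by up
to ±W/2, and the smoothed DTF response by up to ±100 ms, so coarse events
are re-localised on a fine scale: per-channel 80 ms activity series
(short RMS envelope, or lightly smoothed rectified DTF response) pooled
across channels as total energy `sqrt(g₁² + g₂²)` — pooling averages
channel-independent noise at the boundary. Within each coarse event, fine
runs shorter than 80 ms are discarded (noise blips), the longest run is
grown by neighbouring runs within 80 ms (burst fringes fragment near the
noise floor), and each boundary is then extended outward,
hysteresis-style, while the pooled series stays above its rest level —
√2 × rest level for the RMS envelope, which is where burst power equals
noise power. The extension is capped at one fine window: the physical
ramp between the high-threshold crossing and the noise floor is short, and
an uncapped extension occasionally walks through a chance noise stretch.
The 80 ms fine window equals one carrier-envelope coherence time
(≈ 1/bandwidth of the 10–22 Hz band), so a single carrier fade cannot
mimic a burst edge. Refined events shorter than `min_event_duration` are
discarded as noise. Refinement is disabled with `refine_window=0`.

**FDER.** Detected and truth events are matched one-to-one, greedily by
increasing midpoint distance, within a tolerance (default 500 ms — any
value below half the 2 s inter-tap period is unambiguous; the metric's
original context defines none). `FDER = (N_FP + N_FN)/N_all` with `N_all`
the number of detections; the ratio is reported as undefined (with counts)
when nothing was detected against a non-empty truth, and may exceed 1 when
misses dominate.

## Features

Each event yields a centred 1024-sample window per channel (zero-padded at
recording edges). A level-5 wavelet packet transform — full binary tree,
natural (Paley) leaf order, lowpass child first — produces 32 leaves of 32
coefficients, stacked column-wise into a 32×32 matrix. The transform is
implemented directly as a periodized orthonormal filter-bank cascade (no
wavelet library is required): with an orthogonal family and periodic
extension it is an orthonormal change of basis, so leaf energies sum to
the segment energy and the decomposition inverts exactly — both are tested
invariants. Daubechies filters (haar/db1–db4) are embedded at full double
precision; db4 is the default (orthogonal, compactly supported, smooth
enough for band-limited bursts). The per-channel feature vector is the 32
singular values of the leaf matrix, in descending order — a compact,
rotation-invariant summary of how energy distributes over the packet tiling.

### F-value ranking

For feature *i*: `d_{i,j}` is the mean absolute difference over ordered
sample pairs within gesture *j* (normalisation `1/(N(N−1))`); `d_a` is the
mean of `d_{i,j}` over gestures; `d'_a` is the mean absolute difference
over ordered pairs of the per-gesture means (`1/(M(M−1))`). Two ratio
conventions are implemented because the statistic's written form and its
stated interpretation ("bigger F = more important") conflict: `as_printed`
scores `d_a/d'_a`, under which a perfectly discriminative feature (zero
within-gesture spread, distinct means) scores 0; `fisher` scores
`d'_a/d_a`, which matches the interpretation and is the default used for
selection. Degenerate ratios: 0/0 → F = 0 (ranked last among equals);
x/0 → a large finite cap (1e12, with a warning) so the ordering stays
total. Ties break to the lower feature index. Ranking is always fitted on
training data only within each cross-validation fold.

## Classifiers and evaluation

Classifiers are standard scikit-learn estimators behind the package's API:
Gaussian NBC (variance floor 1e-9 × the largest feature variance), KNN
(k = 5, odd, Euclidean, majority vote), and SVM (one-vs-one, polynomial
kernel with γ = 1, coef0 = 0, degree = 3, C = 1, shrinking off, tolerance
1e-3). KNN and SVM consume z-scored features (training-fold statistics);
NBC consumes raw features, since its likelihood normalises scale per
feature. Ties resolve to the lowest class index (thumb < index < middle <
ring < little). Evaluation is stratified k-fold (default 5) with a fixed
shuffle seed; the report aggregates fold confusion matrices and is a pure
function of (data, configuration, seed). `sweep_feature_count` repeats the
evaluation over k = 1..32 features per channel per classifier.

## Synthetic data: what it emulates, and what a green test means

The generator reproduces the *protocol and signal statistics* the pipeline
assumes: 1 kHz two-channel recordings; a leading rest ≥ 5 s (threshold
baseline); 125 taps at 2 s spacing in 5 rounds with 5 s inter-round rests;
bursts of band-limited Gaussian noise (10–22 Hz) under a raised-cosine
envelope, 300–500 ms long, with 50 ms timing jitter and 10% amplitude
jitter; white Gaussian baseline noise; occasional sub-passband drift
(0.5/min, 2σ, 0.02–0.05 Hz) standing in for residual forearm sway — drift
is deliberately below the 0.1 Hz high-pass edge because the acquisition
protocol (forearm resting on a desk) and the filter are jointly supposed
to remove motion artifact. Burst SNR is defined as
`20·log10(peak-envelope burst RMS / noise SD)`, default 20 dB.

Class identity is **constructed**: each gesture has a distinct per-channel
gain pair (geometric steps of ≈1.55, mirrored across channels) and an
emphasis sub-band inside 10–22 Hz. The gain steps were sized from the
feature chain's measured variance budget — the within-class relative
spread of the singular values is 25–30% (carrier realisation, duration
range, amplitude jitter), so ~45% between-class steps are needed for the
default world to be learnable at 4 features/channel. Real per-finger MMG
signatures of the extensor digitorum are not quantitatively characterised
anywhere; no claim of physiological fidelity is made. Consequently a green
end-to-end test establishes that *the implemented chain — detection,
wavelet-packet/SVD features, F-ranking, classifier — transports constructed
class information without loss*, not that the method reaches any particular
accuracy on human data. Five-minute inter-round rests of the original
protocol are shortened to 5 s (rest statistics are stationary; the long
pause exists to avoid participant fatigue). Per-event burst carriers are
drawn independently per event and shared between channels (one muscle
source seen by two sensors).

## Measured behaviour and limitations

* On the default world, both detectors reach FDER = 0 on every one of 20
  held-out seeds, with per-event boundary errors p99 ≈ 65–70 ms. The
  maximum over thousands of events sits near 100 ms: burst onsets/offsets
  whose raised-cosine fringe falls below the noise floor are intrinsically
  ambiguous to about one carrier coherence time, so occasional ~100 ms
  excursions on other seed sets are expected, and boundary precision
  degrades further as SNR approaches 10 dB.
* Detector post-processing (smoothing, edge guard, refinement, hysteresis
  caps) was designed on seeds 100–119 and validated on the disjoint seeds
  0–19 used by the acceptance tests.
* The DTF detector without smoothing (`smooth=0`) reproduces the literal
  rectified-response rule but degenerates on stochastic baselines (see
  above); it is provided for fidelity, not for use.
* Classification accuracy on the synthetic default (≈0.86–0.93 for NBC at
  4 features/channel) is a property of the constructed separability, not a
  prediction for human subjects.
* The CLI and library process complete recordings; there is no streaming/
  online mode, and no notch filtering or adaptive artifact cancellation.
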