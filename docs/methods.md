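# Methods

This note documents the models and procedures implemented in `nervetrack`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmarks do and do not establish.

## Imaging model and coordinate conventions

The pipeline assumes two synchronized single-plane movies of the same
T×H×W geometry: a "red" channel in which every cell carries a
calcium-insensitive nuclear label, and a "green" channel in which the
cytoplasm carries a calcium indicator. Frames are acquired at a fixed rate
(default 10 Hz, chosen so that the fastest body movements — ~5 Hz
contractions — are sampled at least twice per cycle). All positions are
(row, col), 0-based, with pixel centers at integer coordinates; sub-pixel
positions are floats. Stacks are unsigned 16-bit.

## Synthetic movie generator

The generator exists so that every downstream stage can be scored against
exact ground truth. It emulates the statistical structure the pipeline
assumes, with defaults chosen to mimic the target preparation:

- **Cells.** `n_neurons` + `n_nematocytes` cells are placed uniformly
  inside a margin, with a hard-core exclusion radius
  (`min_separation_px` = 8 px = 4× nucleus σ): nuclei are solid objects and
  may not overlap; without this, a neighbour's transients bleed into
  another cell's trace and corrupt per-cell ground truth.
- **Motion.** All cells ride one shared smooth displacement field: a sum of
  6 random 2-D cosine modes (wavelength ≥ `smoothness_px`, default 60 px)
  whose coefficients drift as smoothed random walks, scaled so the field
  amplitude is ≤ `amplitude_px` (6 px) and the per-frame step outside
  contractions is ≤ 1 px. Being smooth and shared, the field is exactly the
  kind of deformation a thin-plate spline can represent. Contraction
  episodes compress the row axis toward the body center so that the fastest
  cells move `max_displacement_px_per_frame` (6 px/frame) — deliberately
  faster than slow-motion gates expect, reproducing the regime where
  tracking fragments.
- **Channel misalignment.** Each cell's green soma is rendered at its
  nucleus position plus a frozen smooth offset field (cosine modes,
  amplitude ≤ 5 px). The field varies across the image, so no global shift
  can undo it; only local search (the sub-ROI stage) can. The 5 px default
  amplitude is an assumption recorded in the config, not a measured fact.
- **Calcium.** Neuron spikes are per-frame Poisson counts
  (`spike_rate`/frame); the noiseless trace follows the AR(2) recursion
  `c_t = g1 c_{t-1} + g2 c_{t-2} + s_t` with the stable default kernel
  (g1, g2) = (1.7, −0.712) (per-frame roots 0.95 and 0.75, i.e. decay
  ~2 s and rise ~0.35 s at 10 Hz), scaled, offset by a baseline glow and
  multiplied by the green bleaching curve. Nematocyte green amplitudes are
  baseline + pure Gaussian noise — bright cells with no spike structure.
- **Nuisances.** Channel-specific per-frame multiplicative photobleaching
  (defaults 0.9995 red / 0.9998 green); per-cell motion-artifact events
  that multiply BOTH channels' spot intensity by (1 − depth) for a few
  frames (common-mode, like axial motion through a confocal plane); Poisson
  shot noise then Gaussian read noise; rounding to uint16 (rounding, not
  truncation, so quantization does not bias argmax ties).
- **Determinism.** One `numpy` generator seeded from `config.seed` drives
  everything; identical config + seed gives bit-identical stacks and truth.

What the generator does **not** emulate: 3-D motion in and out of the focal
plane (artifacts are amplitude dips, not genuine defocus), realistic
tentacle morphology, cell division/death, spatially correlated background,
or indicator saturation. Passing tests on synthetic movies therefore
establishes correctness of the algorithms under the stated model, not
performance on any particular real preparation.

## Detection

The à-trous (undecimated, shift-invariant) wavelet transform convolves with
the separable B3-spline kernel (1/16)[1, 4, 6, 4, 1], dilated by 2^(k−1)
at scale k (mirror boundaries); detail planes are successive differences
and telescope back to the input exactly. Spots of width ~2σ px concentrate
in the detail plane whose scale matches log2 of the spot size — scale 2 for
the default σ = 2 px nuclei.

Detection thresholds a single detail plane at λ·σ̂, with σ̂ the median
absolute deviation of the plane divided by 0.6745 (consistent for Gaussian
noise, robust to the spots themselves). Surviving coefficients form
8-connected components; components under `min_area` = 5 px are noise;
centroids are intensity-weighted (the evaluation metric is center-of-mass
distance, so sub-pixel centroids matter, mask shape does not). The two
hyperparameters are calibrated by grid search maximizing mean
distance-matched f1 over annotated frames, with deterministic tie-breaks
(smaller scale, then smaller λ). The detector interface is a plain callable
so an external segmenter can replace it without touching the rest.

## Tracking

The frame linker is a deliberately simple, fully documented stand-in for
heavier probabilistic trackers, with the same module boundary (detections
in, tracklets out): constant-velocity state per track with steady-state
alpha-beta gains derived from the process/measurement noise ratio;
per-frame global assignment of predictions to detections with costs equal
to Euclidean distance, infinite beyond `gate_radius` (10 px), solved
optimally with a non-link cost equal to the gate; unmatched detections
start tracks (velocity zero at birth); tracks coast on predictions during
misses (state updated only by real detections) and are terminated after
more than `max_missed` = 5 consecutive misses, truncated back to their last
detection. Single-frame tracklets are dropped as detection noise
(`min_length` = 2).

The assignment solver embeds the n×m gated cost matrix into an
(n+m)×(n+m) square problem where every row and column may instead pay the
non-link cost η; `scipy`'s Jonker–Volgenant implementation solves it
exactly, which implies a link survives only if its cost is ≤ 2η. This same
primitive serves the stitcher.

## Tracklet stitching

Premature terminations leave fragments ("tracklets") of each cell's
trajectory. For every frame transition f→f+1 the displacements of all
tracklets alive at both f and f+1 are interpolated by a thin-plate spline
(r²·log r basis plus affine part) with bending regularization α = 10 —
enough smoothing to be robust to linking errors in the control tracklets.
A tracklet's forward ghost is advanced through up to `max_gap` = 50 frames
(5 s at 10 Hz — beyond that, propagation drift makes joins unreliable);
the backward pass is symmetric. The TPS fit itself is `scipy`'s
`RBFInterpolator` (thin-plate kernel, smoothing = α, degree-1 polynomial);
with fewer than 3 non-collinear controls it degrades to a centered
least-squares affine (translation below 3 points), flagged on the result.
Centering matters: an uncentered minimal-norm fit on collinear controls
extrapolates incorrectly.

The stitching cost between tracklets i (ending) and j (starting ≤ max_gap
later) is the **minimum** over shared gap frames of the forward–backward
ghost distance, also evaluated at the partners' boundary frames; the
minimum (rather than mean) is the established choice for this cost and
tolerates one-sided propagation drift. One global assignment with
η = 5 px links fragments; chains merge transitively; gap frames are filled
with the average of the two ghosts and flagged. Detected positions are
never altered. No temporal penalty is applied beyond the max_gap cutoff.

## Calcium linking (sub-ROI tracking)

For each track frame, a 25×25 px window is cut around the nucleus
(out-of-image pixels are zero). The window is smoothed (Gaussian σ = 1 px)
and multiplied by a Gaussian prior centered on the nucleus (σ = 5 px) —
smoothing first, then prior. Up to 5 candidates are extracted by iterated
global maxima, each followed by zeroing a 3 px-radius disc (the suppression
radius is a recorded default; only "a neighbourhood" is prescribed by the
underlying method). On the first frame the top candidate wins; on later
frames the candidate closest to the previous calcium position wins, and the
position is updated as `0.5·pick + 0.5·previous` (the EMA weight is a
recorded default, exposed in config) so a single wrong association cannot
teleport the trace. The raw trace is the mean over integer-grid pixels
within 5 px of the rounded calcium position (81 pixels), a definition
chosen for bit-exact reproducibility; the red control trace uses the same
disc at the nucleus.

The known limitation: during contraction steps of ~6 px/frame the EMA lags
by a few pixels and the extracted intensity dips briefly. The dip is
common-mode-like but originates in tracking, not optics; it is visible in
the integrated demo and discussed under signal processing.

## Signal processing

Fixed order: nematocyte filter → ICA motion correction → detrend → smooth.

- **Nematocyte filter.** A trace is kept iff the D'Agostino–Pearson
  omnibus (skewness + kurtosis) test *rejects* normality at
  p < `normality_p_threshold`; zero-variance or <20-frame traces are
  removed. Spiking neurons produce heavily right-skewed traces (p below
  ~1e-13 in the benchmarks); noise-only cells do not. The threshold is a
  per-dataset user choice: 1e-3 separates cleanly on quiescent recordings,
  while recordings with fast contractions push *every* trace away from
  normality (the sub-ROI lag dips above), so the integrated demo uses 1e-8
  — the populations stay several decades apart and any threshold between
  them gives the same answer.
- **ICA.** Each green trace and its red control are standardized and
  unmixed by 2-component FastICA (tolerance 0.5), run 10 times with
  different seeds; per run the calcium component is the one with larger
  |correlation| to the green trace, and the run whose calcium component has
  the smallest |correlation| to the red control wins. The winner is
  re-oriented and rescaled to the green trace's mean/SD. If no run
  converges the trace passes through unchanged, flagged. The ratiometric
  green/red alternative is implemented for comparison only: when both
  channels approach small values the ratio spikes even as both fall.
- **Detrend.** Zero-phase (forward–backward) 5th-order high-pass
  Butterworth, cutoff 1/`critical_period` cycles per frame (period 100
  frames = 10 s): removes bleaching residue and baseline drift without
  shifting spike times. Traces shorter than 3× the period fall back to mean
  subtraction. Applying the filter twice is a no-op to 0.04% for content
  outside the transition band (edges excluded); broadband signals retain
  transition-band energy that any finite-order filter re-attenuates, so
  exact idempotence is not attainable there.
- **Smooth.** Centered 5-frame rolling mean, window shrinking at the edges.

## Spike inference

`estimate_ar` recovers the per-trace transient model: the noise SD from the
mean one-sided power spectral density over the top quarter of frequencies
(where the slow kernel has no power), the kernel from the Yule–Walker
relations on lag-1..5 autocovariances after subtracting the noise variance
at lag 0 (least squares over the five equations), the baseline as the 8th
percentile of the trace. If the noise-corrected variance is under 5% of the
total, the trace is treated as structureless (kernel 0). Estimated kernels
are projected into the stability region (root magnitudes capped at 0.98).
Accuracy at the benchmark conditions (T = 5000, noise SD 0.1): g1, g2
within ±0.05, noise within ±20%.

`deconvolve` solves the constrained sparse non-negative program: minimize
½‖y − b − c‖² subject to s = Gc ≥ 0 with G the AR(2) difference operator,
parameterized through c = h∗s (h the truncated impulse response) and an L1
penalty λ·Σs on events. The inner problem is solved by FISTA (accelerated
projected proximal gradient with adaptive restart, step 1/L from the
kernel's spectral bound); λ is bisected (12 steps, warm-started) until the
residual norm meets σ̂√T. If even λ = 0 cannot reach the noise level the
constraint is infeasible and a fixed weight λ = σ̂ is used, flagged. A
noiseless unit impulse is recovered at the exact frame with amplitude error
< 1e-2.

`cluster_and_threshold` converts event amplitudes to spikes: Gaussian blur
(σ = 5 frames) of the event train, strict local maxima as candidates,
merging of maxima closer than 5 frames (one calcium transient corresponds
to a single action potential in the target system, so near-coincident
deconvolved events are fragments of one spike; the larger peak keeps the
frame, intensities sum), and an adaptive threshold of
max − 2·SD over the candidate intensities (SD over candidates, not the
full trace — a recorded choice; raw deconvolved amplitudes are used without
re-normalization). Two consequences follow from this design and are
reflected in the benchmarks: the method cannot resolve spikes closer than
about twice the blur width, and a spike within the last blur-width frames
of a trace has no observable transient. Spike-recovery benchmarks therefore
draw spike trains at the stated rate with a 12-frame refractory interval
and a 25-frame end margin; at transient-peak SNR 5 the mean timing F1
(±2 frames) over ten 3000-frame traces is 0.97.

## Evaluation

Detection uses distance-based matching (not IOU): an optimal one-to-one
assignment maximizes the number of predicted–true pairs closer than d
(ineligible pairs carry a large finite penalty so eligible pairs are always
preferred; among equal-cardinality matchings the total distance is
minimized). Tracking accuracy matches each track to the ground-truth cell
it is nearest most often over its first 10 frames, then scores the fraction
of frames within tolerance, reported per track with mean ± SD. Spike timing
uses greedy chronological one-to-one matching within ± tol frames. The f1
arithmetic is the standard harmonic mean, defined as 0 when tp = 0.

## Problem sizes and runtime

The test-suite and acceptance benchmarks use deliberately compact problem
sizes — movies of 10–50 cells, 128–256 px frames, 300–1000 frames;
deconvolution traces of 3000–5000 frames; 200 random assignment instances
up to 6×6 against exhaustive enumeration — chosen so the full suite runs in
a few minutes on one CPU while every stage still operates in its intended
regime (contractions faster than the gate, dropouts longer than the miss
tolerance, SNR at the documented levels).

## Known limitations

- The frame linker is single-hypothesis; dense crossings that a
  multi-hypothesis tracker would disentangle can swap identities. The
  module boundary accepts externally produced tracklets instead.
- Stitching uses geometry only; no appearance features.
- The sub-ROI tracker lags fast contractions by a few pixels (EMA damping),
  briefly depressing extracted intensity.
- The adaptive spike threshold assumes candidate transients of comparable
  amplitude; a single merged double-transient raises the maximum and can
  suppress genuine smaller events in the same trace.
- ICA correction needs the artifact to be genuinely common-mode; artifacts
  that differ between channels (e.g., channel-specific bleaching) are left
  to detrending.
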