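# Methods

This note documents the models, conventions and open design choices behind
`harselect`, in the order data flows through the pipeline.

## Synthetic sensor model

No public corpus of waist-worn smartphone recordings with per-sample
activity labels, fused gravity and calibration samples exists, so the
package generates its own. The signal model is deliberately simple: a sum
of per-activity deterministic templates plus Gaussian noise, chosen so that
every feature family in the registry has at least one activity contrast it
can detect. It is a statistical stand-in, not a biomechanical simulation.

**Axis convention.** Device x and y span the phone face, z points outward
(forward on the pelvis). Upright stance reads gravity ≈ (0, 9.81, 0).

**Posture.** Each activity has a pelvis tilt angle about the device x axis
(stand 0°, sit 30°, lie 85°, walk 5°, stairs ±8–14°, defaults
configurable); gravity in the device frame is the correspondingly rotated
(0, G, 0), normalised so ‖gravity‖ = G exactly at every sample. Mean
z-gravity therefore separates sit from stand by a designed margin — the
contrast the parameter-recovery tests lean on.

**Gait.** During walking, vertical linear acceleration is a sinusoid at
the step frequency with an alternating per-step amplitude envelope
(1 ± asymmetry); forward and lateral components are phase-shifted
sinusoids at the step and stride frequencies. Stair segments add a
`skew·sin²` term whose sign flips between ascent and descent, giving the
vertical signal nonzero skewness of the appropriate sign; ramps get a mild
version of the same. Small-movement activities superimpose low-amplitude
quasi-periodic fidgeting and gyroscope micro-rotation bursts on the static
posture.

**Profiles.** able_bodied (1.9 Hz steps, 2.5 m/s² amplitude, symmetric),
elderly (1.5 Hz, 1.5 m/s², asymmetry 0.05), stroke (1.3 Hz, 1.8 m/s²,
asymmetry 0.4, stronger stair skew, noisier sensor). These are simulation
defaults chosen to be physiologically plausible, not estimates of any real
cohort.

**Transitions.** Each segment boundary is rendered as a 1.5 s cosine
interpolation of pelvis tilt with a movement burst; the x-gyroscope follows
the analytic tilt rate during the sweep. Samples there are labelled
`trans_<from>_to_<to>` — the transition taxonomy is thus configurable
through the script rather than fixed.

**Sampling.** Nominal 50 Hz; the reported rate SD (3.84 Hz) maps to a
spacing SD by the delta method, spacings are i.i.d. Gaussian truncated at
20 % of nominal so timestamps stay strictly increasing.

**Noise.** Gaussian on linear acceleration (default SD 0.15 m/s²), scaled
0.2× on the gyroscope, plus a 0.2° orientation wobble. Raw acceleration is
constructed as gravity + linear acceleration, so the decomposition identity
holds to machine precision by design.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and clothing artefacts, sensor bias
and drift, kinematic consistency between the gyroscope and orientation
outside transitions, video-sync events, and realistic within-activity
variability between repetitions. Conclusions from this package about real
populations are limited to the algorithmic layer: the tests demonstrate
that the pipeline recovers what the generator plants, not that the planted
structure is what real cohorts exhibit.

## Orientation correction

A 10 s standing calibration is scanned with a 1 s window at 0.1 s stride;
the window minimising the summed per-axis SD of *raw* acceleration wins
(earliest on ties). The correction is the shortest-arc (quaternion)
rotation taking that window's mean *gravity* direction onto +y. Raw
acceleration is the scanned channel because it is what a calibration
procedure records; the rotation is built from the fused gravity estimate
because device tilt is what it must cancel — with accelerometer noise, a
rotation built from mean raw acceleration could not satisfy the 1e-6
recovery contract the tests assert. Heading (rotation about the vertical)
is left unconstrained; the shortest arc fixes the residual degree of
freedom. Mean gravity norms below 1 m/s² are rejected as invalid
calibrations.

## Windowing and levels

Windows are half-open 1 s intervals `[t0+i, t0+i+1)`; the count is
`floor(span + nominal dt)`, so a recording sampled over k whole seconds
yields k windows and a trailing partial second is dropped. The window
label is the majority per-sample label, ties broken by earliest occurrence
within the window. Around every state change (annotation runs of differing
stable labels; a transition run counts as the gap between its neighbours) a
±2 s buffer relabels any intersecting window as the composite transition
label; buffered windows feed level 7 only.

Level class maps: L1 mobile = {walk, stairs, ramps}, immobile = {sit,
stand, lie, small moves}; L2 = {sit, stand} excluding small-move variants;
L3 = {sit, stand, lie} including them; L4 = {large movements, stairs} with
ramps folded into large movements (the published class counts — mobile
17607 = L4 16720 + 887 — show the ramp data was retained there); L5 the
five-way mobile split; L6 small-moves yes/no over immobile states; L7
transitions.

## Feature conventions

Fixed, documented choices where the registry's prose descriptions
underdetermine the arithmetic:

- SD/variance/covariance: sample form (ddof=1, `np.cov`); skewness and
  kurtosis: population (biased) estimators, kurtosis non-excess.
  Constant-channel kurtosis is set to the Gaussian baseline 3; constant
  skewness to 0.
- Covariance elements are ordered upper-triangle row-major (xx, xy, xz,
  yy, yz, zz); the registry records the ordering.
- Velocities integrate linear acceleration by the trapezoid rule with zero
  initial velocity per window (no drift carry-over). Feature 43 is the
  final horizontal (x, z) speed of the rotated channel, 44 the final
  vertical velocity, 67/68 the window-mean velocity along the gravity and
  heading directions.
- Heading is the unit vector of the window-mean horizontal (x, z) rotated
  linear acceleration; below norm 1e-6 heading features default to 0, as
  do correlations with a zero-variance component.
- Harmonic means act on absolute values and return 0 when any sample is
  zero.
- Cross rates count sign-sequence changes of vertical (y) linear
  acceleration per second (a sample exactly at zero counts as a crossing
  point); the mean cross rate applies the same count to the mean-removed
  signal. The axis is configurable in principle; y is the vertical axis of
  the device frame.
- Cumulative-sum features report the final cumulative sum (the window
  sum).
- Feature 56 ("moving average of distance from rotated linear
  acceleration") is implemented as the moving average of the per-window
  mean Euclidean distance of samples from their window mean — an
  interpretation, since "distance" is otherwise undefined.
- Features 2 and 21 share one description in the source registry; both are
  computed identically so indices stay aligned with the published tables.
- Moving averages span W = 3 windows (3 s) by default — the shortest span
  that still smooths, consistent with fast real-time response — and
  average over however many windows exist at the start of a recording.
  With W = 1 every moving-average feature equals its plain counterpart.
  The maximum-slope feature is the largest successive difference of the
  smoothed summed-gravity-variance series within the span (0 at cold
  start).

## Selection

- **Relief-F**: Euclidean distances on min-max normalised features; one
  nearest hit and one nearest miss per contrasting class by default
  (configurable k with averaging), misses weighted by P(c)/(1−P(class));
  all occurrences used, no subsampling; neighbour ties resolve to the
  lowest row index. The weight update uses squared differences, as the
  defining formula states.
- **SU-based methods** share equal-frequency discretisation (10 quantile
  bins; constant features collapse to one code), which makes them
  invariant to strictly monotone per-feature transforms. SU values are
  rounded to 12 decimals before ranking so exact ties resolve by feature
  index, not summation order.
- **CFS**: merit uses SU for both feature–class and feature–feature
  correlation by default; a Pearson switch is provided because the
  upstream implementations are ambiguous on this point. Best-first search
  keeps an open heap ordered by merit, expands one-feature extensions,
  deduplicates visited subsets, and stops after five consecutive fully
  expanded non-improving subsets. On small instances it provably matches
  exhaustive enumeration (tested); in general best-first is a heuristic.
- **FCBF**: threshold delta = 0; strictly positive class SU required, so
  all-irrelevant inputs select nothing.
- No class rebalancing before selection: realistic activity data is
  imbalanced and the filters are expected to cope.

## Evaluation

Accuracy is the window-level correct fraction per left-out participant, in
percent. Standardisation is fitted on training folds only. Two modes
exist because the original procedure is ambiguous: `fixed` (select once on
the full level dataset, then cross-validate — what the published tables
imply, with a known selection-leak) and `per_fold` (re-select inside every
training fold — leak-free). The classifiers are evaluation instruments,
not contributions: Gaussian naive Bayes is implemented in closed form
in-repo; the linear SVM (C = 1) and entropy decision tree are
scikit-learn, seeded. Sign tests are exact two-sided binomial tests on
the fold-accuracy differences with ties (|Δ| < 1e-12) dropped; the BH
family is all level × classifier × method comparisons within a population.

## Problem sizes

The shipped study conditions: nine participants (three per profile) on a
198 s circuit covering all eleven base activities and eighteen
transitions, ~1,800 one-second windows in total; planted-recovery runs use
300 × 20 feature matrices with 4 informative columns at a two-SD class
shift (conditionally independent given the class, so their mutual SU stays
below their class SU and all three selectors can in principle recover them);
oracle-equivalence checks use ≤ 30-row instances with ≤ 6 features.

## Known limitations

- Level 7 (transitions) is hard for every feature set, and reduced feature
  subsets lose more accuracy there than anywhere else — the same pattern
  the original study reports on real data. The headline
  "subsets within 2 points of all features" property is therefore asserted
  for the stable-activity levels only; the level-7 margin is reported, not
  asserted.
- Best-first CFS is exact only where exhaustive enumeration is feasible to
  verify; the five-non-improving stop is a search budget, not an
  optimality guarantee.
- The synthetic cohorts are far smaller (9 participants) than a real
  study; LOOCV accuracy estimates are correspondingly coarse and many sign
  tests are underpowered at n = 9 folds.
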