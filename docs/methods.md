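# Methods

This note documents the models, parameter choices and numerical details
behind `driveload`, and what the synthetic-data tests do and do not show
about recorded data.

## Track-based task load

**Position.** The vehicle position is the cumulative trapezoidal integral
of the velocity trace (km/h → m/s), *morphed* so that the reconstructed
distance is exact at every trigger landmark: each inter-trigger interval
is linearly rescaled to match the known distances at its ends, and the
scale of the first/last interval is extended outward. Morphing removes
any multiplicative velocity bias exactly and is idempotent on consistent
data. Distances are meters; spatial bins are half-open
`[i·10, (i+1)·10)`; a drive of length L yields `floor(L/10)` segments.

**Band power.** The continuous wavelet transform uses complex Morlet
kernels on a linear 2–30 Hz grid in 29 steps (1-Hz spacing), with the
number of cycles rising linearly from 3 at 2 Hz to 8 at 30 Hz — a common
compromise between temporal resolution at low and spectral resolution at
high frequencies; both band edges (theta 4–7 Hz, alpha 8–12 Hz) and the
cycle range are configurable. Kernels are L2-normalized; absolute scale
is irrelevant because every channel × frequency trace is z-transformed
over the entire recording before use. Per-segment means are smoothed with
a centered ±5-segment (±50 m) moving average that shrinks symmetrically
at the track edges; segments the vehicle never occupied become NaN and
are excluded. Since the transform is independent per frequency bin, the
cohort-scale path (`segment_band_scores`) computes only the bins inside
the theta/alpha bands and processes one channel at a time — numerically
identical to the composed full-grid operations (a test asserts this) but
with a small, constant memory footprint.

**Terciles.** The load score is `alpha_z − theta_z` per subject and
segment; the across-subject median per segment is rank-partitioned into
terciles (counts differ by at most one; ties break by segment index, so
the partition is deterministic). The highest-score third (alpha-dominant)
is *low* load, the lowest third (theta-dominant) *high* load.

**Behavior.** Steering acceleration is the mean absolute second
difference of the steering angle times the squared sample rate (°/s²).
Event rates are per-segment counts divided by segment dwell time,
averaged within load level — unbiased because the expected count given
dwell time is rate × dwell.

## Preprocessing and ocular components

The band-pass (default 0.1–40 Hz) is zero-phase Butterworth, implemented
as an order-2 high-pass followed by an order-8 low-pass: an IIR edge at
0.1 Hz places poles almost on the unit circle, and orders above 2 leak
numerical noise an order of magnitude above double-precision round-off;
the split keeps the 10-Hz gain within 1% and attenuates 60 Hz below 3%.

Bad channels are detected iteratively under a robust average reference.
A channel is flagged when it is flat (judged on unreferenced data — the
reference would mask flatness), when the robust z of its log10 robust SD
(0.7413 × IQR, insensitive to sparse artifacts such as blinks, which
would otherwise dominate the plain SD of frontal channels) exceeds 5
with the cross-channel spread floored at 0.25 log units (≈ factor 1.8,
so topography differences alone cannot trigger it), or when its maximal
absolute correlation with any other channel is below 0.4 — the latter
only when the recording is spatially correlated overall (median of the
per-channel maxima ≥ 0.5), because the criterion is meaningless for
spatially independent signals. Flagged channels are replaced by
spherical-spline interpolation (mne, standard 10-20 positions) and the
data re-referenced to the average of the good channels, iterating at
most 4 times; more than 25% bad channels aborts.

ICA trains on a 1-Hz high-passed, 250-Hz resampled copy, cut into 1-s
epochs; epochs with peak-to-peak amplitude above 500 µV in any channel
are excluded, and at least 60 s of clean data are required. The
decomposition is FastICA (logcosh, PCA-compressed to the number of
non-corrupt channels minus one, fixed seed); the unmixing matrix applies
directly to the 0.1-Hz filtered 500-Hz data (weight transfer). IC classes
come from a deterministic heuristic: scalp-map correlation with a
bilateral frontopolar template (vertical eye activity, corroborated by
activation kurtosis) and an antisymmetric F7/F8 template (horizontal),
with a negative log-log spectral slope corroborating brain activity;
scores are normalized into pseudo-probabilities, and ICs with a brain
probability of at most 0.30 are removed for EEG analyses. This retains
mixed components by design. Polarity conventions are enforced in place:
blink deflections positive; horizontal topography with F7 − F8 negative,
so positive activation means rightward gaze.

Blink detection fits a four-parameter Gaussian (amplitude, center, width,
offset) around each suprathreshold peak of the vertical eye component and
keeps fits with R² ≥ 0.9 — evaluated over the ±2σ shape region, since the
tails of the ±400 ms fit window contain no blink signal — and width
between 25 and 150 ms; fit windows are clipped at the midpoint toward
neighbouring candidates so close blinks do not corrupt each other.
Saccade candidates are |velocity| maxima (Savitzky–Golay-smoothed
derivative) above 5 robust SDs with a 100-ms refractory period; snippets
cluster by peak-to-peak amplitude (k-means, k = 3, fixed seed) into
small/medium/large templates whose central half must rise monotonically
(within 2% of its range — an automated stand-in for visual inspection).
Detection requires both a sliding Pearson correlation above 0.8 with some
template and a suprathreshold velocity excursion; correlation alone is
scale-invariant and fires on background creep. Onset and offset are the
10%-of-peak-velocity crossings; the offset is emitted as a fixation
onset. Direction is the sign of the position change (medians over 20 ms
before the onset and after the offset, for noise robustness); a saccade
is outward when the offset is farther than the onset from the running
central fixation (coarse running median over 600 s); eccentricity changes
below 5% of the saccade amplitude are labelled `none` and excluded from
type analyses.

## Event-locked measures

ERP epochs span −500..1000 ms. Baselines: blink −400..−200 ms relative to
the fitted Gaussian center; fixation −200..0 ms (saccadic occlusion);
saccade-locked −500..−400 ms — chosen to precede the earliest pre-saccadic
analysis window (−400 ms), which the tonic lateralization occupies; all
configurable. Peak components take the signed extremum matching their
polarity within the detection window on the electrode-cluster average (no
local-peak requirement — appropriate for the smooth averages the jackknife
operates on); slow components take the window mean. Measurement windows
are inclusive at both ends. Jackknife peak estimation measures components
on leave-one-subject-out grand averages; the resulting F statistics are
divided by (n−1)², which is exact for window means (verified to 1%
against the conventional F in simulation) and standard practice for
peaks. Lateralized measures average the contra-minus-ipsi difference over
the posterior pairs P7/P8, PO9/PO10, O1/O2; for right-directed events the
left-hemisphere member is contralateral.

Saccade-locked spectral epochs span −1500..1000 ms: the 3-cycle 2-Hz
Morlet kernel is ≈2.4 s long and must fit inside the epoch. Single-trial
power (same 29-bin grid; mne's Morlet implementation, decimated to
100 Hz) is pair-collapsed into contra and ipsi maps per event; the
difference receives no dB baseline because the subtraction removes power
common to both hemispheres. Pre-saccadic alpha asymmetry is the mean of
the difference map over 8–12 Hz and −800..−50 ms at the parieto-occipital
pair (PO9/PO10 in this montage; configurable).

The cluster-based permutation test is one-sample against zero on subject
maps: cells with |t| above the two-sided critical value at p = .01 join
by 4-connectivity in the freq × time plane; cluster mass is the summed t;
the null is the distribution of the maximal absolute mass over 1000
random sign-flips of whole subjects (positive and negative clusters
handled separately, compared against the common max-|mass| null); p
values use the add-one convention, so the resolution is 1/(n_perm+1) and
p = 0 cannot occur. Zero-variance cells are excluded with a warning. The
implementation is cross-checked against mne's
`permutation_cluster_1samp_test` (identical t maps and cluster masses) in
the test suite.

## Statistics

One- and two-factor fully-within ANOVAs use the standard partitioning,
each effect tested against its subject × effect interaction.
Greenhouse–Geisser epsilon is the covariance-based estimator computed
from orthonormal contrasts of the effect (main effects collapse over the
other factor; the interaction uses the Kronecker contrast), bounded to
[1/df, 1]; both uncorrected and GG-corrected p values are always
reported. The adjusted partial eta squared is
`df₁(F−1)/(df₁F + df₂)`, which is 0 at F = 1, tends to 1 for large F,
never exceeds the unadjusted value, and is floored at 0. The
implementation matches pingouin to numerical precision and a loop-based
sums-of-squares oracle to 1e-10 in the tests.

## The synthetic generator

The generator emulates the statistical structure the analyses assume; it
is the package's test bed, not a driving simulator.

* **Route**: sections (freeway 0.15, rural 0.45, city 0.78, fog 0.90,
  construction 0.82 base demand) smoothed over 30 m with a small 350-m
  sinusoidal modulation, clipped to [0.02, 0.98]; trigger landmarks on an
  even grid (85 for 50 km, scaled with length). The default desk-scale
  cohort is 15 subjects on a 5-km route (500 segments); full 50-km runs
  are a parameter away.
* **Telemetry** (100 Hz): velocity tracks `120 − 80·demand` km/h with a
  2-s first-order lag plus noise; steering is demand-scaled low-passed
  noise. The distance trace is the running sum of the recorded velocity,
  so the velocity integral reproduces the distance by construction.
* **EEG** (500 Hz, 32-channel actiCap layout): spatially correlated 1/f
  background (eight random-topography field sources plus channel noise;
  RMS = 10/SNR µV, so SNR 5 means 2 µV), posterior alpha with amplitude
  `6·(1 − 0.7·demand)` µV split into left/right sources, frontal theta
  `3·(0.5 + 1·demand)` µV, with slow random-walk phase jitter.
* **Eye events**: blinks are 100-µV, σ = 50 ms Gaussians on a frontopolar
  topography; their renewal process (1-s refractory + exponential) keeps
  the realized rate equal to `13·(1 − 0.5·demand)`/min — physiologically
  more regular than Poisson, while counts stay within Poisson intervals.
  Saccades come in outward/return pairs (left/right at random, three
  amplitude classes 20/40/60 µV, 20-ms raised-cosine steps on an F7/F8
  dipole), with dwell 1.1–1.9 s and pair rate `15.2·(1 + 0.12·demand)`
  per minute; the minimum 1.1-s separations keep neighbouring events'
  components out of each other's measurement windows.
* **Neural components**: narrow Gaussians for peak components (latencies
  80–300 ms, widths 13–30 ms, spaced so same-cluster components overlap
  negligibly) and measurement-window-matched plateaus for slow components
  (N1pc 78–122 ms post-fixation; CNV −205..−45 ms and a two-level tonic
  lateralization −410..−45 ms pre-saccade, contralateral channels only);
  amplitudes per load level and saccade type default to values of the
  magnitude observed in simulator driving (a few µV). Contralateral
  posterior alpha is multiplicatively suppressed (factor 0.5) during
  −800..−50 ms before inward saccades only.

`expected_measures` renders each condition's noiseless template through
the same baseline and window rules as the analysis and returns the
resulting value per measure × load × saccade type. This is the recovery
oracle: where components overlap a baseline window (the pre-saccadic CNV
inevitably overlaps the fixation baseline, and Table-pattern "N1"
amplitudes that are positive for inward saccades leave the window minimum
near zero), the expectation reflects that physics rather than the nominal
injected amplitude — exactly as it would in recorded data.

## What the tests show, and problem sizes

Validation runs on synthetic cohorts at deliberate scales: detector
metrics on twenty ~100-s recordings at SNR 10; load-map recovery on ten
15-subject, 5-km cohorts at SNR 20 (mean tercile agreement ≥ 90%);
amplitude recovery on one 15-subject cohort at the full 50-km scale with
background at SNR 5 and oscillations/EOG disabled — the event-locked
subsystem in isolation, because the signed-extremum peak rule carries a
sampling bias that only falls below the ±0.2 µV tolerance once cells
reach a few thousand events, and ongoing alpha is exercised separately by
the load-map and ERSP tests; cluster-test calibration on 200 null
datasets of 15 subjects × 29 × 150 cells. Passing these shows the
pipeline recovers what the generator put in under its assumptions —
stationary topographies, linear demand→power mappings, template-true
blink/saccade shapes. Real recordings violate all of these to some
degree (non-stationary artifacts, imperfect ICA separation, overlapping
oculomotor dynamics), so detector and recovery rates here are upper
bounds, not field performance claims.

## Known limitations

* Vertical saccades and microsaccades are outside the event model; all
  spatial claims are at horizontal-EOG resolution.
* The IC classifier is a deterministic heuristic with the 0.30 brain
  rule; it intentionally keeps mixed components and is not a substitute
  for curated component review on real data.
* The tonic ERL's two plateaus blend over 10 ms at −200 ms, so each
  window mean carries <1% of the other level.
* Lane-keeping measures and between-condition cluster contrasts are not
  implemented.
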