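# Methods

This note records the models, parameter choices, and numerical decisions
behind behavtrace, and what the synthetic study conditions do and do not
establish about real recordings.

## Video pipeline

**Horn–Schunck optical flow.** The flow minimizes the linearized
brightness-constancy residual plus an α²-weighted smoothness term, solved by
Jacobi iterations with the classic 8-neighbor averaging kernel.  Image
gradients use first-order finite differences averaged over the 2×2×2 cube of
the two-frame volume.  Defaults: α = 1.0, 100 iterations, early stop when
the mean flow update falls below 1e−4.  The iteration is implemented here
because no installed library provides Horn–Schunck (scikit-image ships
TV-L1 and iterative Lucas–Kanade only), and the first-order variant is the
method this pipeline is built around.  The energy can be tracked per
iteration (`return_energy=True`); on the test fixtures it decreases
monotonically.

Horn–Schunck is a linearization: it underestimates displacements much
larger than the dominant texture wavelength.  Frame pairs are therefore
taken three frames apart (120 ms at 25 fps) so that slow motion still
produces measurable flow, and the synthetic actor carries a smooth texture
(wavelengths 9–17 px) so that displacements of a few pixels stay within the
linear regime.

**Binarization threshold.** 0.3 px per frame-pair interval by default,
exposed in every API.  The value is a package choice — small enough to catch
slow movers in the synthetic scenes; real cameras will want it tuned to
sensor noise.

**Silhouette and edge band.** The silhouette is the logical intersection of
two consecutive binarized flows (the last flow step reuses its
predecessor's partner).  Interior flow vectors are chaotic for a first-order
method, so the direction statistics use only a band around the silhouette
contour: the contour (silhouette minus its 8-neighbor erosion) dilated with
a grid-approximated disk of radius `band_px // 2` (band ≈ 4–5 px wide at the
default `band_px = 4`).

**Direction histogram.** Angle of (u, v) is atan2(−v, u) — the image y axis
points down, so 0° is motion toward the image right (bin B1) and 90° toward
the top (B3); B5 is leftward motion.  Bin i spans [45(i−1) − 22.5°,
45(i−1) + 22.5°), i.e., the printed lower bound of the first bin is read as
−22.5°.  Counts are unweighted (magnitude is already gated by binarization)
and L1-normalized per flow step; a step with no contributing pixel yields an
all-zero histogram flagged "undetermined" rather than a normalized one.

## Accelerometer chain

Stages run in this fixed order: baseline offset subtraction (per-axis mean
over a 10 s motionless window) → centered moving average over 0.2 s (window
forced to an odd sample count; edges use the shrunken overlap, so the
closed-form 1/w noise-variance reduction holds away from the edges) →
per-subject normalization by the maximal |value| over all of the subject's
measurements → affine map v ↦ (v+1)/2 into [0, 1] (the nominally open lower
endpoint is treated as notational; an exact −1 maps to 0) → plain fourfold
subsampling to 25 Hz (the 0.2 s average is the anti-alias stage).  Summary
statistics use the sample (n−1) standard deviation.

Fall detection triggers when |ax|+|ay|+|az| exceeds 2.5 g (default; the
threshold is an empirical device property), with a 1 s refractory merge.

**Pan–Tompkins.** 5–15 Hz second-order Butterworth bandpass applied
zero-phase, derivative, squaring, 150 ms moving-window integration, then the
classic adaptive signal/noise running thresholds (SPKI/NPKI, threshold =
NPKI + 0.25·(SPKI − NPKI), 0.2 s refractory between candidate peaks).
Detections are refined to the dominant deflection of the bandpassed signal
within one integration window; zero-phase filtering keeps the R wave in
place, so a ±50 ms match tolerance is comfortable.  Heart rate is 60 divided
by the median RR interval; a flat or beat-free trace reports NaN with an
`undefined` flag instead of a number.

## Fusion and evaluation

The combined vector concatenates the 8-bin histogram and the 3-axis
processed sample with no cross-modality rescaling beyond each chain's own
normalization — both blocks already live in [0, 1].  Classification is
k-NN with Euclidean distance, k = 1 by default (leave-one-out selection is
provided; ties go to the smallest k).  Exact distance ties resolve to the
lowest training-record index, which makes predictions independent of
training-set order except at ties.  Video histograms are held zero-order
between flow steps when aligned to the 25 Hz accelerometer grid.  The
classification window default of 160 s is kept as configured in the study
protocol, although it is hard to reconcile with ~6.4 s movies; it is a
config value, not a hard-coded constant.

The learning/testing split draws exactly 10 records per (activity, subject)
cell with a seeded generator; with the shipped repetition table this gives
2,400 + 4,874 records.

**Synthetic indoor benchmark.** Rendering ~7,000 movies is out of
proportion for a feature-level property, so the fusion benchmark generates
features directly: each of the 12 activities has an 8-bin histogram
prototype and a 3-axis prototype, with deliberate modality-specific
ambiguity — 1a/2a identical and 3a/4a nearly identical on the
accelerometer, 3b/4b identical on video — plus per-subject offsets and
Gaussian modality noise (defaults 0.05 per bin, 0.03 per axis, chosen to
put single-modality accuracy in the 80–90 % range).  The fused vector
resolves every pair, so combined accuracy exceeds the better single
modality by construction of the conditions, and the benchmark checks that
the classifier realizes this.  This demonstrates the fusion mechanism, not
field performance: real histograms have temporally correlated noise and
real accelerometer features subject-specific morphology that the prototypes
do not model.

## Synchronization

Motion envelopes: |a| magnitude for the wearable, per-flow-step mean |OF|
for the premise stream (a velocity proxy — alignment by cross-correlation is
invariant to monotone channel transforms of matched events, and
differentiating the sparse flow-step series would amplify quantization).
Salient sections are maximal runs at or above the 95th percentile of the
trailing 900 s history.  The salient section is detected on the wearable
envelope, padded by 0.5 s of context, and slid across the premise envelope;
the Pearson correlation is evaluated at every integer lag on a 100 Hz grid.
100 Hz (not the 25 Hz common rate one might expect) is used because the
recovery requirement is one sample on the accelerometer grid, and a 40 ms
lag quantum cannot represent, e.g., a 0.5 s delay.  The estimated delay
replaces the previous one only when the correlation exceeds 0.70 ("over
70 %" is read as normalized correlation); every decision is appended to an
audit log.  Compensation subtracts the estimated delay plus the source's
nominal processing delay from the timestamps.

The synthetic dual streams script a 1.5 s jump with a smooth sin² speed
profile and a matching 3 g accelerometer bump, which is what makes 10 ms
recovery possible from an 8.3 Hz flow-step envelope; sharp-onset events
would be recovered to roughly one flow step instead.

## Behavioral distance and danger detection

The state distance d[i,j] is the *squared* Euclidean distance between
w-vectors, as the distance-matrix definition specifies (the surrounding
prose says "Euclidean distance"; the equation wins, and a `root_distance`
switch provides the square-rooted variant).  The DTW recursion uses steps
{(1,0),(0,1),(1,1)} with unit weights, fixed endpoints, no warping window,
and diagonal preference when backtracking ties.  Costs are not
length-normalized; category thresholds must be chosen with sequence length
in mind.

Pattern statistics use the population (n) standard deviation so a single
occurrence reports 0; successor lists are observed transition frequencies
ordered by probability.  Clustering is scipy average-linkage agglomeration
on pairwise DTW costs cut at a cophenetic threshold.

The 12 activity codes collapse to 6 movement classes (the a/b phases of one
movement are one elementary pose); "undetermined" completes P = 7 and is
assigned full mass when the nearest neighbor is farther than the
undetermined threshold.  "Undetermined" never violates pose permissions.

N/S/D/C categorization thresholds are three DTW-cost cut points (defaults
0.5 / 2 / 6, calibrated on the synthetic one-hot patterns where disjoint
sequences of length l cost exactly 2·max(l₁, l₂)); the source material
names the categories but no numeric rule, so the bands are configurable
per subject.  Each permission violation escalates the category one band,
saturating at C.  "Discrimination" and "supervision" name the same mode.
Supervision never mutates the safe-pattern library; learning never emits
alerts; every S/D/C event in supervision produces exactly one
detail-recording action.

## Synthetic data: scope and limits

The actor is a textured rigid rectangle with an analytic texture evaluated
at continuously shifted coordinates (true sub-pixel motion, anti-aliased
edges) — enough to exercise flow, binarization, intersection, bands and
histograms, but it has no articulation, so per-limb activities differ only
by scripted global motion.  Accelerometer templates are hand-designed
bursts (amplitude, axis mix, shape) distinct per activity; they are
reproducible fixtures, not biomechanics.  ECG is a sum of Gaussian PQRST
waves at exact RR intervals.  Consequently, passing tests establish that
the algorithms are implemented correctly and behave as designed under
controlled conditions; they do not certify recognition rates on real
recordings.

Problem sizes used by the test suite and acceptance script — 64×64 to
160×64 px scenes, 12–15 s dual streams, 20 seeds per injected delay, 1,000
DTW oracle pairs, 2,000-segment Markov records — are chosen to make the
checks statistically meaningful while keeping a full run in tens of
seconds.

## Degenerate inputs

Empty silhouette → empty band, flagged all-zero histogram; constant
envelope → no salient sections; flat ECG → undefined heart rate; all-zero
accelerometer corpus, non-overlapping outdoor streams, unknown zones, empty
safe-pattern libraries, and deficient split cells all raise with the
offending item named rather than producing numbers.
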