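# behavtrace

Tools for tracing human behavior at home from two complementary sensor
families: a premise-embedded camera whose frames are reduced on-device to
optical-flow pose features (no image ever leaves the premise), and a
body-worn sensor set (3-axis accelerometer, single-lead ECG, GPS).  The
package targets ambient-assisted-living research: recognizing activities of
daily living, keeping the two sensor streams on a common clock, summarizing
behavior as statistical patterns, and flagging departures from a person's
learned safe behavior.

Because recordings of monitored subjects cannot be redistributed, the
package ships a first-class synthetic-data module that renders scripted
silhouette movies and generates accelerometer/ECG/GPS traces with exact
ground truth, so every stage is testable end to end.

## What it computes

**Video pose features.** Dense Horn–Schunck optical flow between frames
three apart (120 ms at 25 fps).  The flow modulus |OF| is binarized with a
constant threshold; the silhouette is the intersection of two consecutive
binarized flows; the flow directions on the silhouette's ~4 px dilated edge
band are aggregated into an 8-bin histogram (B1..B8, centers 0°, 45°, …,
315°; B1 = motion to the right of the scene, B5 = to the left), normalized
to sum to 1.  Stacking histograms over flow steps gives a time–angle matrix.

**Accelerometer chain.** Offset subtraction (10 s motionless baseline per
axis) → 0.2 s moving average → per-subject division by the maximal absolute
value over all of that subject's measurements → affine map to [0, 1] →
fourfold decimation 100 Hz → 25 Hz, yielding the [x y z] feature vector.
Plus |ax|+|ay|+|az| threshold fall detection, Pan–Tompkins QRS detection
(bandpass → derivative → squaring → moving-window integration → adaptive
thresholds), haversine GPS speed, and per-axis MEAN/STD/MIN/MAX summaries.

**Fusion and recognition.** The combined feature vector is
[B1 … B8 X Y Z]; classification is k-nearest-neighbor with k = 1 (selected
by leave-one-out).  The evaluation protocol draws 10 records per (activity,
subject) cell into the learning set — with the shipped per-subject
repetition table that is exactly 2,400 learning and 4,874 testing records —
and reports per-activity, per-subject, and overall accuracy.

**Synchronization.** Wearable and premise streams are aligned by
cross-correlating motion envelopes (|a| magnitude vs. per-step mean |OF|)
around salient sections (top 5 % of envelope values over a trailing 15 min
history).  A new delay is accepted only when the normalized correlation
exceeds 0.7, so ordinary movement cannot retune the clock.

**Behavioral distance and danger detection.** A subject state is a convex
combination of P = 7 elementary poses (6 movement classes + "undetermined")
with weights w_p.  Two state sequences are compared by dynamic time warping
over d[i,j] = Σ_p (w_p,1[i] − w_p,2[j])², with monotone paths through
{(1,0),(0,1),(1,1)}.  Pattern statistics (mean/std duration,
probability-ordered successors), DTW-based clustering, a two-level
zone/status behavioral record, premise permission rules (forbidden poses
per zone, appliance time limits), and the setup / learning / supervision
life cycle with N/S/D/C behavior categories build on that distance.

## Worked example

Render a scripted scene (walk right, jump, walk left) with a wearable trace,
extract features, and estimate the stream delay:

```sh
python -c "
from behavtrace import synthdata as sd
import pathlib
segs = (sd.Segment('3a', 1.0, 1.5, direction_deg=0, speed=8.0),
        sd.Segment('jump', 6.0, 1.5, direction_deg=90, speed=18.0, profile='bump'),
        sd.Segment('3b', 10.0, 1.5, direction_deg=180, speed=8.0))
pathlib.Path('script.json').write_text(sd.ActivityScript('V1', segs, tail=3.0).to_json())
"
behavtrace synth --script script.json --out demo --seed 1 --frame-size 64x64
behavtrace video-features --frames demo/frames --out feats.csv
behavtrace summarize --trace demo/accel.csv
behavtrace sync --video demo/frames --accel demo/accel.csv
```

prints

```
wrote 362 frames and 1450 accelerometer samples to demo
wrote 119 histogram columns to feats.csv
      MEAN   STD   MIN   MAX
ACCX -0.00  0.06 -0.23  0.24
ACCY  1.16  0.57  0.97  4.00
ACCZ  0.00  0.01 -0.03  0.04
delay estimate -0 ms (correlation 0.983)
```

The y axis carries the 1 g gravity offset and the 4 g jump peak; `feats.csv`
holds one normalized B1..B8 histogram per 120 ms flow step (all-zero rows
are static scene stretches); the delay estimate is 0 for a stream pair
generated without an injected lag, with correlation 0.98 well above the 0.7
acceptance gate.

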