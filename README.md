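# myogrid

Real-time hand-gesture recognition from high-density surface EMG (HD-EMG),
built for myoelectric prosthesis control research: a 32-channel electrode
grid is read as a stream of 4×8 *muscle activation maps*, classified every
sampling period (1 ms) by a compact convolutional network, and smoothed
into a system-level output by a 200-slot majority-vote buffer.  The package
also implements the two-phase transfer-learning setup protocol, Teager-
Kaiser-Energy (TKE) motion-onset detection, and the transition-aware
real-time evaluation metrics needed to assess such a controller honestly —
positive predictive value over whole trials, motion selection time and
motion completion time.  A seeded synthetic HD-EMG generator stands in for
human recordings, so every experiment here is reproducible end to end from
a seed.

## Who this is for

Researchers in myoelectric control / neuroprosthetics who want a reference
implementation of a streaming HD-EMG recognition pipeline and — just as
importantly — of *real-time* evaluation metrics that score gesture
transitions rather than offline frame accuracy.

## The pipeline and its numbers

1. **Front-end** — per-channel band-pass (20–450 Hz) and a causal 15-sample
   mean-absolute-value (MAV) filter; samples map row-major onto the 4×8
   grid (`myogrid.preprocessing`).
2. **Classifier** — `GridConvNetClassifier`, a small CNN (two 3×3
   convolutions, global pooling, one hidden dense layer, 6-way head) with a
   scikit-learn estimator interface.  Transfer learning
   (`myogrid.transfer`): pre-train on a multi-subject cohort, adapt all
   layers once per new user, then fine-tune **only the head** per session —
   the feature layers stay bit-identical.
3. **Voting** — per-sample predictions fill a 200-vote FIFO; the output is
   the majority label, optionally gated by a minimum vote count θ (default
   102) below which the previous output is held (`myogrid.voting`).
4. **Metrics** — each trial (rest → gesture → rest) is scored per sample:
   true negatives before onset, false negatives while the change has not
   yet propagated (perceived latency), true/false positives once the output
   moves.  PPV = TP/(TP+FP); selection time ST is onset → first correct
   output; completion time CT is onset → tenth correct output
   (`myogrid.evaluation`, `myogrid.onset`).

Two identities pin down the system's responsiveness at 1 kHz: a saturated
200-slot buffer flips on the **101st** consecutive new vote, and through
the 15-sample MAV transient the worst-case end-to-end response spans
**116** sampling instants.

## Worked example

```python
import myogrid as mg
from myogrid import experiment

base = experiment.pretrain_cohort(seed=1)          # 8 synthetic subjects
user = mg.make_subject(777)                        # a held-out user
clf = experiment.adapt_user(base, user, seed=5)    # one-time all-layer fit
row = experiment.run_gesture_trial(clf, user, gesture=1, seed=12345)
print(row)
```

prints (numbers from this exact seeded run):

```
{'gesture': 1, 'seed': 12345, 'detected_onset_ms': 1001.0,
 'ppv_plain': 1.0, 'st_plain': 113.0, 'ct_plain': 122.0,
 'ppv_thresholded': 1.0, 'st_thresholded': 124.0, 'ct_thresholded': 133.0}
```

The trial holds gesture 1 for 3 s between 1 s rests.  TKE detects the
contraction onset 1 ms after the scripted 1000 ms instant; both voting
modes score a perfect PPV of 1.0; the thresholded vote is a few ms slower
to select the motion (124 vs 113 ms) — the conservatism/latency trade-off
the threshold exists to buy.  In both modes CT − ST = 9 ms, the constant
offset between completion and selection when the output stays correct.

A full synthetic user study (12 users × 5 active gestures × 5 trials) is
one call, `experiment.run_user_study(seed=1)`, or from the shell:

```sh
myogrid protocol-times        # setup-time accounting of both protocols
myogrid simulate --subject-seed 3 --gesture 1 --out trial.h5
myogrid onset --in trial.h5
```

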