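# Methods

This note documents the models, conventions and design choices behind
`myogrid`, in the spirit of a package methods appendix: what is simulated,
what is computed, which knobs matter, and what the tests do and do not
demonstrate.

## Synthetic HD-EMG model

Real HD-EMG of the forearm, recorded with a 4×8 dry-electrode cuff at
1 kHz, shows gesture-specific spatial distributions of activity: each
voluntary contraction recruits muscles under a characteristic subset of
electrodes.  The generator reduces this to an amplitude-modulation model.
Per channel *c*:

    x_c(t) = carrier_c(t) · ( σ₀ + g_c(label(t)) · env(t) )

* `carrier_c` — independent white Gaussian noise band-passed to 20–450 Hz
  (the standard surface-EMG bandwidth), giving a zero-mean, band-limited
  stochastic carrier.
* `σ₀` — stationary noise-floor scale (default 0.01, i.e. roughly 40 dB
  below a full contraction; the "high-SNR" regime the evaluation targets).
* `g_c(label)` — the subject's spatial gain for the gesture, drawn once
  per subject as a sum of 2–3 Gaussian activation foci on the grid with
  peak gain ≈ 1.  Active-gesture maps are re-drawn until pairwise cosine
  similarity < 0.95; the neutral gesture (label 4, open hand/rest) has a
  zero map — rest produces no contraction.
* `env(t)` — a truncated logistic onset/offset envelope: zero before a
  segment boundary, 10 % at the boundary, 90 % of plateau `ramp_ms` later
  (default 200 ms, the scale of voluntary contraction times).  The
  annotated onset is exactly the envelope's departure from baseline, so
  detectors can be tested for non-anticipation.

Inter-subject variability comes from independent template draws per
subject seed; inter-session variability (`session_variant`) applies
multiplicative log-normal jitter (σ = 0.15) to every template entry plus
an optional 1-column circular shift of the grid, emulating cuff
re-donning displacement.

**What the generator does *not* model:** motor-unit action-potential
trains and their superposition statistics, electrode–skin impedance
drift, crosstalk between neighboring channels, fatigue, force/amplitude
nonlinearity.  Passing results on this generator show the pipeline's
*mechanics* are correct and that the learning system behaves as designed
under controlled separability; they do not predict human-subject
performance figures.

## Recording protocols

Two named protocols generate labeled training data, mirroring a practical
setup routine: `initial` = 6 gestures × 5 s × 5 repetitions = 150 s of
active recording; `reduced` = 6 gestures × 2 s × 3 repetitions = 36 s.
Off-time rest of the same duration separates the holds.  Frames are
labeled by the scripted gesture; the first 2×`ramp_ms` of every active
segment are excluded from the steady-state mask used for training (ramp
frames are ambiguous by construction).  Offline frame extraction uses the
zero-phase band-pass variant; everything streamed at inference time is
strictly causal.

## Front-end

* Band-pass: 4th-order Butterworth, 20–450 Hz, causal (`sosfilt`) in
  streaming mode, forward-backward (`sosfiltfilt`) offline only.
* MAV: causal sliding mean of the rectified signal, window 15 samples.
  `out[n] = mean |x[n−14..n]|`; a step from 0 to c reaches exactly c after
  15 samples, which is the "15 ms transient" term of the latency budget.
  The first 14 outputs of a stream use the partial-window mean and are
  flagged as warm-up.
* Grid mapping: channel k → (k div 8, k mod 8), bijective; no physical
  electrode geometry beyond the 4×8 adjacency is assumed.

## Classifier and transfer learning

`GridConvNetClassifier` is a deliberately small NumPy CNN: conv 3×3 (8
filters, same padding) → ReLU → conv 3×3 (16) → ReLU → global average
pool → dense 32 → ReLU → dense 6-way head.  The parameter partition is
explicit: everything before the head is the *feature extractor*, the final
dense layer is the *classifier head*.  Training: Adam (lr 1e-3), batch
256, cross-entropy, early stopping on an internal stratified 15 %
validation split (patience 5, max 30 epochs), best-on-validation snapshot
restored.  All randomness flows from `random_state`; two fits with the
same seed are bit-identical.

Input normalization divides frames by a single amplitude scale estimated
on the training data (mean per-frame peak).  During training, each frame
is additionally scaled by a log-uniform factor in [0.25, 2.0] (amplitude
augmentation): contraction intensity is effort-dependent and uncontrolled
in deployment, and during transitions the spatial pattern passes through
scaled-down versions of itself, so the label must be carried by the
pattern, not the absolute amplitude.  Without this, transition frames sit
outside the steady-state training distribution and can hold a wrong label
long enough to flip the vote buffer.

Transfer protocol: `pretrain` fits a fresh network on ≥ 2 subjects
(refusing a cohort that contains the target user); `adapt_new_user`
warm-starts from the pretrained parameters and trains **all** layers on
the user's initial-protocol data; `finetune_session` warm-starts and
trains the **head only** on the reduced-protocol data of a new session —
the feature layers are verified bit-identical before the result is
returned.

## Streaming inference

A 200-slot FIFO of per-sample predictions, pre-filled with the neutral
label at stream start; the majority is recomputed on every push, one
output per 1 ms sample.  Ties for the maximum retain the last output
(holding the current gesture is safer than a spurious movement).  In
thresholded mode the output changes only when the majority label holds at
least θ votes (default 102 of 200); otherwise the previous valid output is
held.  An incremental count array implements the buffer; the tests check
it against a full-recount oracle on randomized streams.

### Latency conventions

Two constants characterize the ideal-conditions response at 1 kHz:

* *Votes to flip*: a buffer saturated with one label needs 101 consecutive
  new-label votes before the new label holds the majority (101 > 99).
* *End-to-end span*: 116 sampling instants, decomposed as 15 MAV-transient
  instants + 101 vote instants.  The measurement convention
  (`step_response_latency`): the input change instant coincides with a
  sampling instant whose sample still reads the pre-step value (sampling
  precedes the step within that instant); latency counts sampling instants
  inclusively from the change instant to the first changed output.  The
  worst case takes every frame inside the MAV transient to be classified
  as the previous gesture.

## Onset detection

TKE: ψ[n] = x[n]² − x[n−1]·x[n+1], computed per channel on the
band-passed signal, zero at the two boundary samples, then averaged over
the 32 channels.  The detection threshold is mean + 2.5 × SD of the
*unsmoothed* channel-mean TKE over a pre-trial baseline window (default
500 ms); detection monitors the 15-sample moving-mean-smoothed series and
requires it to stay above threshold for a 10 ms debounce.  Calibrating on
the raw series matters: the smoothed series is autocorrelated over its
window, so sustained excursions above its own 2.5 σ level are common under
stationary noise, whereas against the raw-series SD the smoothed energy
essentially never crosses without a contraction (0/200 seeded noise
streams trigger) while a real onset, hundreds of times above the floor,
is detected within ~1–2 ms of the scripted instant.

## Evaluation metrics

Each trial is rest → gesture → rest with a scripted onset and release.
Per-sample scoring over the **whole** trial:

| phase | output = initial | output = target | other |
|---|---|---|---|
| before onset | TN | FP | FP |
| onset → release | FN | TP | FP |
| after release | TP¹ | FN | FP |

¹ only when the output actually selected the target during the hold — a
genuine detected release; an output that never moved off the initial
label earns TNs throughout (pure latency), never TPs.

The release transition is scored with roles swapped (returning to rest is
itself a gesture change).  Pre-onset outputs that differ from the initial
label are false positives — an unwanted activation before the user moved
is precisely the error class the metric should expose.  PPV = TP/(TP+FP)
is therefore insensitive to latency (FN) and undefined when no positive
was emitted; the undefined case propagates as NaN and is mapped to 0 only
in windowed reporting (no prediction towards the target occurred in that
window).  ST/CT use the TKE-detected onset as their time anchor, falling
back to the scripted onset; scoring truth always uses the scripted
timeline.  `score_outputs` also offers a post-onset-only mode for
sensitivity analyses; full-trial scoring is the default.

## Setup-time accounting

Installation is a fixed 3 min; recording doubles the active protocol
duration to cover off-time (plus a 2 min mid-protocol break in the long
initial protocol): 150 s → 7 min, 36 s → 72 s = 1.2 min.  Training
minutes default to the documented reference CPU medians of the two
workflows (full training 44.59 min, session fine-tuning 1.58 min); these
are reference constants for the accounting identities — wall-clock
training time on any given machine is recorded in `training_log_` but
never asserted.  Totals: 54.59 vs 5.78 min, an 89.4 % reduction.

## Study conditions and problem sizes

The synthetic study mirrors the structure of a real-time user evaluation:
an 8-subject pretraining cohort, 12 evaluation users, 5 trials for each of
the 5 active gestures (3 s holds between 1 s rests), high SNR (σ₀ = 0.01).
Training frames are subsampled with stride 25 (adjacent 1 ms MAV frames
are nearly identical), keeping a full study run in minutes on one CPU.
All seeds derive from a single study seed through named `SeedSequence`
streams, so every table cell is regenerable from the seed alone.

## Known limitations

* The generator's amplitude-modulation model cannot produce the
  non-stationarities (fatigue, electrode lift-off, sweat) that drive real
  inter-session degradation; the transfer-learning gains measured here are
  therefore qualitative, not calibrated to human data.
* The CNN architecture is a compact stand-in honoring the feature/head
  partition; no architecture search was performed.
* Gesture release (offset) detection is taken from the trial script; only
  onset is detected from the signal.
* Thresholded voting is compared with plain voting per trial; no claim is
  made about optimality of θ = 102 beyond the conservatism it encodes.
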