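"""End-to-end synthetic study harness.

Reproduces the study structure on synthetic users: a pretraining cohort,
per-user all-layer adaptation, then seeded contraction trials (rest ->
gesture -> rest) streamed through the causal front-end, the CNN and the
majority-vote buffer, scored with the transition-aware metrics.  Default
sizes mirror the study conditions: an 8-subject pretraining cohort, 12
evaluation users, 5 trials per active gesture with 3 s holds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, onset as onset_mod, preprocessing, synthetic, transfer, voting
from .model import GridConvNetClassifier

N_PRETRAIN_SUBJECTS = 8
N_USERS = 12
TRIALS_PER_GESTURE = 5
ACTIVE_GESTURES = (1, 2, 3, 5, 6)
TRAIN_STRIDE = 25  # adjacent 1 ms MAV frames are nearly identical
HOLD_MS = 3000.0
REST_MS = 1000.0


def _seed_pool(seed: int, stream: int, n: int) -> np.ndarray:
    """n deterministic 31-bit seeds for one named sub-stream of ``seed``."""
    return np.random.SeedSequence([int(seed), int(stream)]).generate_state(n) % (2**31)


def training_arrays(
    subject: synthetic.SubjectModel,
    protocol: str,
    seed: int,
    stride: int = TRAIN_STRIDE,
):
    """Steady-state (frames, labels) from a recording protocol, subsampled."""
    ds = synthetic.build_protocol_dataset(subject, protocol, seed)
    X, y = ds.steady_frames()
    return X[::stride], y[::stride]


def pretrain_cohort(
    seed: int,
    n_subjects: int = N_PRETRAIN_SUBJECTS,
    protocol: str = "initial",
    stride: int = TRAIN_STRIDE,
    **clf_params,
) -> GridConvNetClassifier:
    """Pre-train the base network on a cohort of synthetic subjects."""
    subject_seeds = _seed_pool(seed, 0, n_subjects)
    data_seeds = _seed_pool(seed, 1, n_subjects)
    datasets = {}
    for i in range(n_subjects):
        subj = synthetic.make_subject(int(subject_seeds[i]))
        datasets[subj.subject_id] = training_arrays(subj, protocol, int(data_seeds[i]), stride)
    return transfer.pretrain(datasets, random_state=int(_seed_pool(seed, 2, 1)[0]), **clf_params)


def adapt_user(
    base: GridConvNetClassifier,
    subject: synthetic.SubjectModel,
    seed: int,
    protocol: str = "initial",
    stride: int = TRAIN_STRIDE,
    **fit_params,
) -> GridConvNetClassifier:
    """One-time all-layer adaptation of the base network to one user."""
    X, y = training_arrays(subject, protocol, seed, stride)
    return transfer.adapt_new_user(base, X, y, random_state=seed % (2**31), **fit_params)


def run_gesture_trial(
    clf: GridConvNetClassifier,
    subject: synthetic.SubjectModel,
    gesture: int,
    seed: int,
    hold_ms: float = HOLD_MS,
    rest_ms: float = REST_MS,
    ramp_ms: float = 200.0,
    capacity: int = voting.DEFAULT_CAPACITY,
    threshold: int = voting.DEFAULT_THRESHOLD,
) -> dict:
    """One contraction trial, evaluated under plain and thresholded voting.

    Returns a dict with per-mode PPV/ST/CT plus the detected onset.  The
    scripted onset is the scoring ground truth; the TKE-detected onset
    anchors the timing metrics (falling back to the scripted instant if
    detection fails).
    """
    script = synthetic.TrialScript(
        ((synthetic.NEUTRAL_LABEL, rest_ms), (gesture, hold_ms), (synthetic.NEUTRAL_LABEL, rest_ms)),
        ramp_ms=ramp_ms,
    )
    stream = synthetic.synthesize_trial(subject, script, seed)
    frames = preprocessing.stream_to_frames(stream)  # causal streaming front-end
    preds = clf.predict(frames)

    ann = evaluation.TrialAnnotation(
        target_label=gesture, onset_ms=rest_ms, release_ms=rest_ms + hold_ms
    )
    bandpassed = preprocessing.bandpass(stream)
    cfg = onset_mod.OnsetConfig(noise_window_ms=min(800.0, rest_ms * 0.8))
    detected = onset_mod.detect_onset(bandpassed, onset_mod.calibrate_threshold(bandpassed, cfg), cfg)
    onset_ms = detected if detected is not None else ann.onset_ms

    row = {"gesture": gesture, "seed": seed, "detected_onset_ms": detected}
    for mode, theta in (("plain", None), ("thresholded", threshold)):
        out = voting.vote_stream(preds, capacity=capacity, threshold=theta)
        counts = evaluation.score_outputs(out, ann)
        row[f"ppv_{mode}"] = evaluation.ppv(counts)
        row[f"st_{mode}"] = evaluation.selection_time(out, ann, onset_ms=onset_ms)
        row[f"ct_{mode}"] = evaluation.completion_time(out, ann, onset_ms=onset_ms)
    return row


def run_user_study(
    seed: int,
    n_users: int = N_USERS,
    trials_per_gesture: int = TRIALS_PER_GESTURE,
    gestures=ACTIVE_GESTURES,
    base: GridConvNetClassifier = None,
    n_pretrain_subjects: int = N_PRETRAIN_SUBJECTS,
    **trial_params,
) -> pd.DataFrame:
    """Full synthetic user study; one row per (user, gesture, trial).

    Pre-trains once on a disjoint cohort, adapts each evaluation user with
    the initial protocol, then runs the seeded contraction trials.
    """
    if base is None:
        base = pretrain_cohort(seed, n_subjects=n_pretrain_subjects)
    user_seeds = _seed_pool(seed, 10, n_users)
    adapt_seeds = _seed_pool(seed, 11, n_users)
    trial_seeds = _seed_pool(seed, 12, n_users * len(gestures) * trials_per_gesture)

    rows = []
    k = 0
    for u in range(n_users):
        subject = synthetic.make_subject(int(user_seeds[u]))
        clf = adapt_user(base, subject, int(adapt_seeds[u]))
        for g in gestures:
            for t in range(trials_per_gesture):
                row = run_gesture_trial(clf, subject, g, int(trial_seeds[k]), **trial_params)
                row.update({"user": u, "trial": t})
                rows.append(row)
                k += 1
    return pd.DataFrame(rows)


def study_summary(trials: pd.DataFrame) -> dict:
    """Headline statistics of a study table (PPV/ST under both modes)."""
    return {
        "n_trials": int(len(trials)),
        "median_ppv_plain": float(trials["ppv_plain"].median()),
        "mean_ppv_plain": float(trials["ppv_plain"].mean()),
        "median_ppv_thresholded": float(trials["ppv_thresholded"].median()),
        "median_st_plain_ms": float(trials["st_plain"].dropna().median()),
        "median_st_thresholded_ms": float(trials["st_thresholded"].dropna().median()),
        "perfect_trials_plain": int((trials["ppv_plain"] == 1.0).sum()),
        "perfect_trials_thresholded": int((trials["ppv_thresholded"] == 1.0).sum()),
    }
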