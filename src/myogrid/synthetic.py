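"""Synthetic high-density surface-EMG generator.

Emulates a 32-channel (4x8 grid) HD-EMG recording at 1 kHz: each hand
gesture excites a subject-specific spatial amplitude pattern over the
electrode grid, voluntary contractions ramp in and out with a sigmoidal
envelope, and a stationary noise floor is always present.  The raw signal
per channel is a band-limited zero-mean noise carrier, amplitude-modulated
by ``baseline + template_gain * envelope``.

All generators are pure functions of ``(seed, parameters)``: the same seed
reproduces bit-identical streams.  The simulator targets *learnability*
(distinct, stable spatial patterns per gesture), not physiological fidelity
of motor-unit action potentials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

N_CHANNELS = 32
GRID_SHAPE = (4, 8)
SAMPLE_RATE = 1000.0  # Hz; one prediction per sampling period (1 ms)
GESTURE_LABELS = (1, 2, 3, 4, 5, 6)
NEUTRAL_LABEL = 4  # open hand / rest posture

#: named recording protocols: (hold seconds per gesture, repetitions)
PROTOCOLS = {"initial": (5.0, 5), "reduced": (2.0, 3)}


@dataclass(frozen=True)
class GestureTemplate:
    """Per-subject spatial amplitude pattern of one gesture.

    ``amplitude_map`` holds non-negative activation gains (baseline-relative,
    arbitrary units) on the 4x8 electrode grid.  The neutral gesture
    (label 4) has an identically ~0 map: rest produces no contraction.
    """

    subject_id: str
    gesture_label: int
    amplitude_map: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude_map, dtype=float)
        if amp.shape != GRID_SHAPE:
            raise ValueError(f"amplitude_map must be {GRID_SHAPE}, got {amp.shape}")
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ValueError("amplitude_map entries must be finite and >= 0")
        if self.gesture_label not in GESTURE_LABELS:
            raise ValueError(f"gesture_label must be in {GESTURE_LABELS}")
        object.__setattr__(self, "amplitude_map", amp)


@dataclass(frozen=True)
class TrialScript:
    """Ordered gesture schedule of one trial.

    ``segments`` is a sequence of ``(gesture_label, duration_ms)``;
    ``ramp_ms`` is the sigmoidal onset/offset transition duration (the
    envelope reaches 90% of plateau within ``ramp_ms`` of a boundary).
    """

    segments: tuple
    ramp_ms: float = 200.0

    def __post_init__(self) -> None:
        segs = tuple((int(lab), float(dur)) for lab, dur in self.segments)
        for lab, dur in segs:
            if lab not in GESTURE_LABELS:
                raise ValueError(f"invalid gesture label {lab}; must be in {GESTURE_LABELS}")
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
        if self.ramp_ms <= 0:
            raise ValueError("ramp_ms must be > 0")
        object.__setattr__(self, "segments", segs)

    @property
    def total_ms(self) -> float:
        return sum(d for _, d in self.segments)


@dataclass(frozen=True)
class Segment:
    """Annotated span of a stream: ``label`` held over [start_ms, end_ms)."""

    label: int
    start_ms: float
    end_ms: float
    active: bool = True  # False for off-time rest between scripted holds


@dataclass
class EmgStream:
    """Uniformly sampled multichannel EMG with its ground-truth timeline."""

    samples: np.ndarray  # (T, 32) raw values
    sample_rate: float = SAMPLE_RATE
    segments: tuple = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be (T, {N_CHANNELS}), got {x.shape}")
        self.samples = x

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sample_rate

    def onsets(self) -> list:
        """Scripted onset instants: starts of non-neutral segments (ms)."""
        return [s.start_ms for s in self.segments if s.label != NEUTRAL_LABEL]


@dataclass
class SubjectModel:
    """A synthetic user: one template per gesture plus noise parameters.

    ``noise_floor_sd`` sets the stationary baseline carrier amplitude
    (per-channel), ``session_jitter`` the log-normal sigma of multiplicative
    template perturbation applied between recording sessions.
    """

    subject_id: str
    templates: dict  # label -> GestureTemplate
    noise_floor_sd: float = 0.01
    session_jitter: float = 0.15

    def __post_init__(self) -> None:
        if sorted(self.templates) != sorted(GESTURE_LABELS):
            raise ValueError(f"subject needs exactly one template per label in {GESTURE_LABELS}")
        if self.noise_floor_sd <= 0:
            raise ValueError("noise_floor_sd must be > 0")

    def gains(self, label: int) -> np.ndarray:
        """Row-major per-channel gain vector (32,) for ``label``."""
        return self.templates[label].amplitude_map.reshape(N_CHANNELS)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / (na * nb))


def _blob_map(rng: np.random.Generator) -> np.ndarray:
    """Random spatial pattern: 2-3 Gaussian activation foci on the grid."""
    rows, cols = np.mgrid[0 : GRID_SHAPE[0], 0 : GRID_SHAPE[1]]
    amp = np.zeros(GRID_SHAPE)
    for _ in range(rng.integers(2, 4)):
        r0 = rng.uniform(0, GRID_SHAPE[0] - 1)
        c0 = rng.uniform(0, GRID_SHAPE[1] - 1)
        sig = rng.uniform(0.8, 1.8)
        gain = rng.uniform(0.5, 1.3)
        amp += gain * np.exp(-(((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sig**2)))
    # normalize peak activation to a subject-specific scale around 1
    amp *= rng.uniform(0.8, 1.2) / amp.max()
    return amp


def make_subject(
    seed: int,
    n_gestures: int = 6,
    noise_floor_sd: float = 0.01,
    session_jitter: float = 0.15,
    max_cosine: float = 0.95,
) -> SubjectModel:
    """Draw a deterministic synthetic subject.

    The five active gestures receive pairwise-distinct spatial amplitude
    maps (cosine similarity < ``max_cosine``); the neutral gesture (label 4)
    has a zero map.
    """
    if n_gestures != len(GESTURE_LABELS):
        raise ValueError(f"n_gestures must be {len(GESTURE_LABELS)}")
    rng = np.random.default_rng(seed)
    subject_id = f"synth-{seed}"
    maps: dict = {}
    for label in GESTURE_LABELS:
        if label == NEUTRAL_LABEL:
            maps[label] = np.zeros(GRID_SHAPE)
            continue
        for _ in range(200):
            cand = _blob_map(rng)
            if all(
                _cosine(cand, prev) < max_cosine
                for lab, prev in maps.items()
                if lab != NEUTRAL_LABEL
            ):
                maps[label] = cand
                break
        else:  # pragma: no cover - 200 draws always suffice on a 32-cell grid
            raise RuntimeError("could not draw a sufficiently distinct template")
    templates = {
        lab: GestureTemplate(subject_id, lab, amp) for lab, amp in maps.items()
    }
    return SubjectModel(subject_id, templates, noise_floor_sd, session_jitter)


def session_variant(
    subject: SubjectModel, seed: int, column_shift: int = 0
) -> SubjectModel:
    """Inter-session view of a subject.

    Applies multiplicative log-normal jitter (sigma ``subject.session_jitter``)
    to every template entry and optionally a circular column shift of the
    grid (sensor re-donning displacement), exercising transfer learning and
    the classifier's translational tolerance.
    """
    rng = np.random.default_rng(seed)
    templates = {}
    for lab, tpl in subject.templates.items():
        amp = tpl.amplitude_map * rng.lognormal(0.0, subject.session_jitter, GRID_SHAPE)
        if lab == NEUTRAL_LABEL:
            amp = np.zeros(GRID_SHAPE)
        if column_shift:
            amp = np.roll(amp, column_shift, axis=1)
        templates[lab] = GestureTemplate(tpl.subject_id, lab, amp)
    return dataclasses.replace(subject, templates=templates)


def _carrier(rng: np.random.Generator, n: int, sample_rate: float) -> np.ndarray:
    """Band-limited zero-mean noise carrier, (n, 32)."""
    white = rng.standard_normal((n, N_CHANNELS))
    sos = sps.butter(4, [20.0, 450.0], btype="bandpass", fs=sample_rate, output="sos")
    return sps.sosfilt(sos, white, axis=0)


def _envelope(n: int, boundary: int, ramp: float) -> np.ndarray:
    """Truncated logistic transition: 0 before ``boundary``, reaches 0.9 at
    ``boundary + ramp`` samples, ~1 thereafter."""
    from scipy.special import expit

    t = np.arange(n, dtype=float)
    k = 2.0 * np.log(9.0) / ramp
    env = expit(k * (t - boundary - ramp / 2.0))
    env[t < boundary] = 0.0
    return env


def synthesize_trial(
    subject: SubjectModel,
    script: TrialScript,
    seed: int,
    sample_rate: float = SAMPLE_RATE,
    active_mask: tuple = None,
) -> EmgStream:
    """Render one scripted trial into a raw 32-channel stream.

    Gains cross-fade between consecutive segment templates with the
    sigmoidal envelope anchored at each boundary, so the annotated segment
    start is exactly the instant the envelope departs baseline.
    ``active_mask`` optionally flags which segments are scripted holds
    (True) versus off-time rest (False); defaults to all-active.
    """
    if active_mask is None:
        active_mask = tuple(True for _ in script.segments)
    if len(active_mask) != len(script.segments):
        raise ValueError("active_mask length must match script segments")
    n = int(round(script.total_ms * sample_rate / 1000.0))
    ramp = script.ramp_ms * sample_rate / 1000.0

    # per-channel modulation gains over time
    gains = np.tile(subject.gains(script.segments[0][0]), (n, 1))
    segments = []
    start = 0.0
    prev_label = script.segments[0][0]
    for i, (label, dur) in enumerate(script.segments):
        end = start + dur
        segments.append(Segment(label, start, end, bool(active_mask[i])))
        if i > 0 and label != prev_label:
            b = int(round(start * sample_rate / 1000.0))
            delta = subject.gains(label) - subject.gains(prev_label)
            gains += _envelope(n, b, ramp)[:, None] * delta[None, :]
        prev_label = label
        start = end

    rng = np.random.default_rng(seed)
    samples = _carrier(rng, n, sample_rate) * (subject.noise_floor_sd + gains)
    return EmgStream(samples, sample_rate, tuple(segments))


@dataclass
class ProtocolDataset:
    """Labeled activation-frame set produced by a recording protocol.

    ``frames`` are MAV-filtered 4x8 maps at every sampling period of the
    *active* (scripted-hold) portions; ``steady`` flags the frames outside
    onset/offset ramps that are safe to use as training labels.
    """

    frames: np.ndarray  # (N, 4, 8) float32
    labels: np.ndarray  # (N,) int
    steady: np.ndarray  # (N,) bool
    subject_id: str
    protocol: str

    def steady_frames(self):
        """(X, y) restricted to steady-state frames."""
        return self.frames[self.steady], self.labels[self.steady]

    @property
    def n_samples(self) -> int:
        return int(self.labels.shape[0])


def build_protocol_dataset(
    subject: SubjectModel,
    protocol: str,
    seed: int,
    ramp_ms: float = 200.0,
    steady_margin_ms: float = None,
    low_hz: float = 20.0,
    high_hz: float = 450.0,
    mav_window: int = 15,
) -> ProtocolDataset:
    """Run a named recording protocol on a synthetic subject.

    ``initial``: 6 gestures x 5 s x 5 repetitions = 150 s of active
    recording; ``reduced``: 6 gestures x 2 s x 3 repetitions = 36 s.  An
    equal amount of off-time rest separates the holds.  Frames are produced
    offline (zero-phase band-pass + MAV) and labeled by the scripted
    gesture; the first ``steady_margin_ms`` of every active segment (ramp
    plus settling, default twice the ramp) is excluded from the steady mask.
    """
    from . import preprocessing  # local import to avoid a cycle

    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {sorted(PROTOCOLS)}")
    hold_s, reps = PROTOCOLS[protocol]
    hold_ms = hold_s * 1000.0
    if steady_margin_ms is None:
        steady_margin_ms = 2.0 * ramp_ms

    seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    all_frames, all_labels, all_steady = [], [], []
    for rep in range(reps):
        segs, active = [], []
        for g in GESTURE_LABELS:
            segs.append((NEUTRAL_LABEL, hold_ms))  # off-time rest
            active.append(False)
            segs.append((g, hold_ms))
            active.append(True)
        script = TrialScript(tuple(segs), ramp_ms=ramp_ms)
        stream = synthesize_trial(
            subject, script, int(seeds[rep]), active_mask=tuple(active)
        )
        frames = preprocessing.stream_to_frames(
            stream, low_hz=low_hz, high_hz=high_hz, window=mav_window, zero_phase=True
        )
        fs = stream.sample_rate
        for seg in stream.segments:
            if not seg.active:
                continue
            i0 = int(round(seg.start_ms * fs / 1000.0))
            i1 = int(round(seg.end_ms * fs / 1000.0))
            all_frames.append(frames[i0:i1])
            all_labels.append(np.full(i1 - i0, seg.label, dtype=np.int64))
            steady = np.ones(i1 - i0, dtype=bool)
            steady[: int(round(steady_margin_ms * fs / 1000.0))] = False
            all_steady.append(steady)

    return ProtocolDataset(
        frames=np.concatenate(all_frames).astype(np.float32),
        labels=np.concatenate(all_labels),
        steady=np.concatenate(all_steady),
        subject_id=subject.subject_id,
        protocol=protocol,
    )
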