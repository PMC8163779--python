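"""Streaming majority-vote inference.

Per-sample classifier predictions are accumulated as votes in a 200-slot
FIFO; the system-level output is the majority label, recomputed on every
push (one output per sampling period).  In thresholded mode the output
changes only when the majority label holds at least ``threshold`` votes
(default 102 of 200); otherwise the previous valid output is retained —
the system "holds the current gesture" rather than act on a weak majority.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .synthetic import GESTURE_LABELS, NEUTRAL_LABEL

DEFAULT_CAPACITY = 200
DEFAULT_THRESHOLD = 102


class VoteBuffer:
    """FIFO of the last ``capacity`` per-sample predictions.

    At stream start the buffer is pre-filled with ``initial_label``
    (neutral rest by default), so early outputs are well defined.  Ties for
    the maximum count retain the last emitted output.
    """

    def __init__(
        self,
        capacity: int = DEFAULT_CAPACITY,
        threshold: int = None,
        initial_label: int = NEUTRAL_LABEL,
        labels=GESTURE_LABELS,
    ):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if threshold is not None and not (1 <= threshold <= capacity):
            raise ValueError("threshold must lie in [1, capacity]")
        self.capacity = capacity
        self.threshold = threshold
        self.labels = tuple(labels)
        self._max_label = max(self.labels)
        if initial_label not in self.labels:
            raise ValueError(f"initial_label must be in {self.labels}")
        self.votes = deque([initial_label] * capacity, maxlen=capacity)
        self.counts = np.zeros(self._max_label + 1, dtype=np.int64)
        self.counts[initial_label] = capacity
        self.last_output = initial_label

    def push(self, label: int) -> int:
        """Push one prediction, return the updated system output."""
        label = int(label)
        if label not in self.labels:
            raise ValueError(f"invalid label {label}; must be in {self.labels}")
        evicted = self.votes[0]
        self.votes.append(label)  # deque with maxlen drops the left element
        self.counts[evicted] -= 1
        self.counts[label] += 1

        top = int(self.counts.max())
        winners = np.flatnonzero(self.counts == top)
        if winners.size != 1:
            candidate = self.last_output  # tie: retain the current gesture
        else:
            candidate = int(winners[0])
        if self.threshold is None:
            self.last_output = candidate
        elif self.counts[candidate] >= self.threshold:
            self.last_output = candidate
        return self.last_output


def push_and_vote(buffer: VoteBuffer, label: int) -> int:
    """Functional alias of :meth:`VoteBuffer.push`."""
    return buffer.push(label)


def vote_stream(
    predictions,
    capacity: int = DEFAULT_CAPACITY,
    threshold: int = None,
    initial_label: int = NEUTRAL_LABEL,
) -> np.ndarray:
    """Run the vote buffer over a whole prediction stream.

    Returns one system output per input prediction; output at time ``t``
    depends only on predictions at times ``<= t``.
    """
    buf = VoteBuffer(capacity=capacity, threshold=threshold, initial_label=initial_label)
    preds = np.asarray(predictions, dtype=np.int64)
    out = np.empty_like(preds)
    push = buf.push
    for i, p in enumerate(preds):
        out[i] = push(int(p))
    return out


def run_stream(
    state,
    frames,
    capacity: int = DEFAULT_CAPACITY,
    threshold: int = None,
    initial_label: int = NEUTRAL_LABEL,
) -> np.ndarray:
    """Classify a time-ordered frame sequence and majority-vote the result.

    ``state`` is either a fitted classifier (``predict``) or a callable
    mapping the frame array to per-sample labels (e.g. a ground-truth stub).
    """
    if callable(getattr(state, "predict", None)):
        preds = state.predict(np.asarray(frames))
    elif callable(state):
        preds = state(np.asarray(frames))
    else:
        raise TypeError("state must expose .predict or be callable")
    return vote_stream(preds, capacity=capacity, threshold=threshold, initial_label=initial_label)


def majority_flip_votes(capacity: int = DEFAULT_CAPACITY, threshold: int = None) -> int:
    """Consecutive new-label votes needed to flip a saturated buffer.

    Fills the buffer with one label, then pushes the other label one vote
    at a time, recomputing the majority on every push, and returns the
    number of pushes at which the output changes (101 for a 200-slot plain
    majority buffer).
    """
    old, new = NEUTRAL_LABEL, 1
    buf = VoteBuffer(capacity=capacity, threshold=threshold, initial_label=old)
    for k in range(1, capacity + 1):
        if buf.push(new) == new:
            return k
    raise RuntimeError("buffer never flipped")  # pragma: no cover


def step_response_latency(
    mav_window: int = 15,
    capacity: int = DEFAULT_CAPACITY,
    amp_before: float = 0.0,
    amp_after: float = 1.0,
) -> int:
    """Worst-case end-to-end flip latency of the full pipeline, in samples.

    An ideal noise-free amplitude step is driven through the MAV front-end
    and the pre-filled vote buffer with a per-sample classifier that is
    perfect on settled frames (worst case: frames inside the MAV transient
    keep the previous label).  The change instant coincides with a sampling
    instant whose sample still reads the pre-step amplitude; the returned
    latency counts sampling instants inclusively from the change instant to
    the first changed system output.  With a 15-sample MAV and a 200-slot
    buffer this spans 15 transient instants + 101 vote instants = 116.
    """
    from .preprocessing import mav_filter

    old, new = NEUTRAL_LABEL, 1
    change = capacity + 3 * mav_window  # buffer genuinely saturated by then
    total = change + capacity + 2 * mav_window
    x = np.full(total, float(amp_before))
    x[change + 1 :] = amp_after  # the sample at the change instant reads old
    env = mav_filter(x, window=mav_window)
    # worst case: only fully settled envelopes are recognized as the new gesture
    preds = np.where(np.isclose(env, amp_after, rtol=0.0, atol=1e-12), new, old)
    out = vote_stream(preds, capacity=capacity, initial_label=old)
    flips = np.flatnonzero(out != old)
    if flips.size == 0:  # pragma: no cover
        raise RuntimeError("output never flipped")
    return int(flips[0]) - change + 1
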