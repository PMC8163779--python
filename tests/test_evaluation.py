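"""Transition-aware scoring, PPV, selection/completion time, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myogrid as mg
from myogrid import evaluation as ev


def rule_table_oracle(outputs, ann):
    """Independent per-sample application of the four transition rules."""
    tp = fp = tn = fn = 0
    selected = any(
        out == ann.target_label
        for t, out in enumerate(outputs)
        if ann.onset_ms <= t < ann.release_ms
    )
    for t, out in enumerate(outputs):
        if t < ann.onset_ms:
            if out == ann.initial_label:
                tn += 1
            else:
                fp += 1
        elif t < ann.release_ms:
            if out == ann.initial_label:
                fn += 1
            elif out == ann.target_label:
                tp += 1
            else:
                fp += 1
        else:  # release transition: roles swapped
            if out == ann.target_label:
                fn += 1
            elif out == ann.initial_label:
                # a genuine detected release only if the target was selected
                tp += 1 if selected else 0
                tn += 0 if selected else 1
            else:
                fp += 1
    return ev.TransitionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def ideal_outputs(ann, n, latency=0):
    out = np.full(n, ann.initial_label)
    out[int(ann.onset_ms) + latency : int(ann.release_ms) + latency] = ann.target_label
    return out


class TestScoreOutputs:
    def test_perfect_trial_has_full_ppv(self):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        counts = mg.score_outputs(ideal_outputs(ann, 500), ann)
        assert counts.fp == 0 and counts.tp > 0
        assert mg.ppv(counts) == 1.0

    def test_stuck_at_initial_is_pure_latency(self):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        counts = mg.score_outputs(np.full(500, 4), ann)
        assert counts.tp == 0 and counts.fp == 0 and counts.fn > 0
        assert np.isnan(mg.ppv(counts))

    def test_hand_built_transition_with_one_error(self):
        # 20 samples: onset at 5, release at 15, one wrong label mid-transition
        ann = ev.TrialAnnotation(target_label=1, onset_ms=5, release_ms=15)
        out = np.array([4] * 5 + [4, 3, 1, 1, 1, 1, 1, 1, 1, 1] + [4] * 5)
        counts = mg.score_outputs(out, ann)
        assert (counts.tn, counts.fn, counts.fp, counts.tp) == (5, 1, 1, 13)
        assert counts == rule_table_oracle(out, ann)

    @settings(max_examples=200, deadline=None)
    @given(
        outs=st.lists(st.integers(1, 6), min_size=10, max_size=40),
        onset=st.integers(1, 5),
        span=st.integers(2, 4),
    )
    def test_matches_rule_table_oracle(self, outs, onset, span):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=onset, release_ms=onset + span)
        assert mg.score_outputs(outs, ann) == rule_table_oracle(outs, ann)

    def test_counts_partition_all_samples(self):
        rng = np.random.default_rng(0)
        out = rng.integers(1, 7, 300)
        ann = ev.TrialAnnotation(target_label=5, onset_ms=80, release_ms=220)
        assert mg.score_outputs(out, ann).total == 300

    def test_misaligned_annotation_rejected(self):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        with pytest.raises(ValueError, match="misaligned"):
            mg.score_outputs(np.full(300, 4), ann)

    def test_latency_never_lowers_ppv(self):
        # injecting false-negative runs (held initial label) leaves PPV at 1.0
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        for latency in (0, 40, 120):
            out = ideal_outputs(ann, 500, latency=latency)
            assert mg.ppv(mg.score_outputs(out, ann)) == 1.0
        # and the formula itself ignores the negative counts entirely
        assert mg.ppv(ev.TransitionCounts(tp=7, fp=3, tn=0, fn=0)) == mg.ppv(
            ev.TransitionCounts(tp=7, fp=3, tn=500, fn=900)
        )


class TestPpv:
    def test_arithmetic(self):
        assert mg.ppv(ev.TransitionCounts(tp=9, fp=1)) == 0.9
        assert mg.ppv(ev.TransitionCounts(tp=0, fp=5)) == 0.0
        assert np.isnan(mg.ppv(ev.TransitionCounts(tp=0, fp=0, tn=10, fn=3)))


class TestSelectionCompletionTime:
    def _ann(self):
        return ev.TrialAnnotation(target_label=2, onset_ms=1000, release_ms=4000)

    def test_selection_time_first_correct(self):
        ann = self._ann()
        out = np.full(5000, 4)
        out[1300:4000] = 2
        assert mg.selection_time(out, ann) == 300.0

    def test_never_correct_is_none(self):
        ann = self._ann()
        out = np.full(5000, 4)
        assert mg.selection_time(out, ann) is None
        assert mg.completion_time(out, ann) is None

    def test_completion_is_tenth_correct(self):
        ann = self._ann()
        out = np.full(5000, 4)
        out[1100:1119:2] = 2  # correct every 2 ms from onset+100
        assert mg.completion_time(out, ann) == 118.0

    def test_constant_nine_period_offset_when_post_st_correct(self):
        ann = self._ann()
        for start in (1000, 1237, 2500):
            out = np.full(5000, 4)
            out[start:4000] = 2
            st_ms = mg.selection_time(out, ann)
            ct_ms = mg.completion_time(out, ann)
            assert ct_ms - st_ms == 9.0

    def test_onset_override_shifts_reference(self):
        ann = self._ann()
        out = np.full(5000, 4)
        out[1300:4000] = 2
        assert mg.selection_time(out, ann, onset_ms=1100) == 200.0


class TestWindowedPpv:
    def test_default_zero_before_first_positive(self):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        out = ideal_outputs(ann, 500, latency=120)
        vals = mg.windowed_ppv(out, ann, [0, 100, 200])
        assert vals[0] == 0.0 and vals[1] == 1.0

    def test_correct_steady_state_window_is_one(self):
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        vals = mg.windowed_ppv(ideal_outputs(ann, 500), ann, [50, 250])
        assert vals[0] == 1.0

    def test_window_concatenation_consistency(self):
        rng = np.random.default_rng(3)
        ann = ev.TrialAnnotation(target_label=2, onset_ms=100, release_ms=400)
        out = rng.integers(1, 7, 500)
        codes = ev.classify_samples(out, ann)
        edges = [0, 70, 150, 300]
        # union of the windows equals a single recount over the union span
        tp = np.count_nonzero(codes[100:400] == ev.TP)
        fp = np.count_nonzero(codes[100:400] == ev.FP)
        per_window_tp = sum(
            np.count_nonzero(codes[100 + a : 100 + b] == ev.TP)
            for a, b in zip(edges[:-1], edges[1:])
        )
        per_window_fp = sum(
            np.count_nonzero(codes[100 + a : 100 + b] == ev.FP)
            for a, b in zip(edges[:-1], edges[1:])
        )
        assert (per_window_tp, per_window_fp) == (tp, fp)


class TestAggregate:
    def test_summary_arithmetic(self):
        df = pd.DataFrame(
            {"gesture": [1, 1, 1], "ppv": [1.0, 1.0, 0.8], "st": [100.0, 200.0, None]}
        )
        agg = mg.aggregate(df, by="gesture")
        assert agg.loc[1, "median_ppv"] == 1.0
        assert agg.loc[1, "mean_ppv"] == pytest.approx(0.9333, abs=1e-3)
        assert agg.loc[1, "perfect_trials"] == 2
        assert agg.loc[1, "median_st"] == 150.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mg.aggregate(pd.DataFrame(columns=["gesture", "ppv", "st"]))

    def test_annotation_validation(self):
        with pytest.raises(ValueError):
            ev.TrialAnnotation(target_label=9, onset_ms=0, release_ms=10)
        with pytest.raises(ValueError):
            ev.TrialAnnotation(target_label=2, onset_ms=50, release_ms=40)
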