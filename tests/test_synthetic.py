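"""Synthetic HD-EMG generator: determinism, templates, protocols."""

import numpy as np
import pytest

import myogrid as mg
from myogrid import preprocessing as pp
from myogrid import synthetic as syn


def _cosine(a, b):
    return np.dot(a.ravel(), b.ravel()) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestMakeSubject:
    def test_deterministic_given_seed(self):
        a, b = mg.make_subject(1), mg.make_subject(1)
        for lab in syn.GESTURE_LABELS:
            np.testing.assert_array_equal(
                a.templates[lab].amplitude_map, b.templates[lab].amplitude_map
            )

    def test_different_seeds_differ(self):
        a, b = mg.make_subject(1), mg.make_subject(2)
        assert any(
            not np.array_equal(a.templates[l].amplitude_map, b.templates[l].amplitude_map)
            for l in syn.GESTURE_LABELS
            if l != syn.NEUTRAL_LABEL
        )

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_active_templates_pairwise_distinct(self, seed):
        subj = mg.make_subject(seed)
        active = [l for l in syn.GESTURE_LABELS if l != syn.NEUTRAL_LABEL]
        for i, la in enumerate(active):
            for lb in active[i + 1 :]:
                cos = _cosine(
                    subj.templates[la].amplitude_map, subj.templates[lb].amplitude_map
                )
                assert cos < 0.95

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_neutral_template_quiet(self, seed):
        subj = mg.make_subject(seed)
        active_max = max(
            subj.templates[l].amplitude_map.max()
            for l in syn.GESTURE_LABELS
            if l != syn.NEUTRAL_LABEL
        )
        assert subj.templates[syn.NEUTRAL_LABEL].amplitude_map.max() < 0.05 * active_max


class TestSynthesizeTrial:
    def test_same_seed_bit_identical(self):
        subj = mg.make_subject(3)
        script = mg.TrialScript(((4, 500.0), (1, 800.0)))
        a = mg.synthesize_trial(subj, script, 9)
        b = mg.synthesize_trial(subj, script, 9)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, mg.synthesize_trial(subj, script, 10).samples)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            mg.TrialScript(((7, 1000.0),))
        with pytest.raises(ValueError, match="duration"):
            mg.TrialScript(((1, 0.0),))

    def test_neutral_trial_stays_at_noise_floor(self):
        subj = mg.make_subject(3)
        stream = mg.synthesize_trial(subj, mg.TrialScript(((4, 2000.0),)), 1)
        mav = pp.mav_filter(np.abs(stream.samples))[100:]  # past warm-up
        assert mav.max() < 3 * subj.noise_floor_sd

    def test_onset_crosses_tke_threshold_within_ramp(self):
        subj = mg.make_subject(3)
        script = mg.TrialScript(((4, 1000.0), (1, 3000.0), (4, 1000.0)), ramp_ms=200.0)
        stream = mg.synthesize_trial(subj, script, 5)
        bp = pp.bandpass(stream)
        t = mg.detect_onset(bp, mg.calibrate_threshold(bp))
        assert t is not None and 1000.0 <= t <= 1250.0

    def test_annotation_records_scripted_onsets(self):
        subj = mg.make_subject(3)
        script = mg.TrialScript(((4, 1000.0), (2, 2000.0), (4, 500.0)))
        stream = mg.synthesize_trial(subj, script, 5)
        assert stream.onsets() == [1000.0]
        assert stream.n_samples == 3500


class TestProtocolDataset:
    @pytest.mark.parametrize(
        "protocol,expected", [("initial", 150_000), ("reduced", 36_000)]
    )
    def test_active_sample_counts(self, protocol, expected):
        subj = mg.make_subject(5)
        ds = mg.build_protocol_dataset(subj, protocol, seed=1)
        assert ds.n_samples == expected

    def test_class_balance_and_labels(self):
        subj = mg.make_subject(5)
        ds = mg.build_protocol_dataset(subj, "reduced", seed=1)
        labels, counts = np.unique(ds.labels, return_counts=True)
        assert list(labels) == list(syn.GESTURE_LABELS)
        assert len(set(counts)) == 1  # equal active duration per label

    def test_steady_mask_excludes_ramps(self):
        subj = mg.make_subject(5)
        ds = mg.build_protocol_dataset(subj, "reduced", seed=1)
        assert 0 < ds.steady.sum() < ds.n_samples
        # steady frames of active gestures carry clear amplitude
        X, y = ds.steady_frames()
        active = y != syn.NEUTRAL_LABEL
        assert X[active].max(axis=(1, 2)).min() > 10 * subj.noise_floor_sd

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="protocol"):
            mg.build_protocol_dataset(mg.make_subject(5), "weekly", seed=1)


class TestSessionVariant:
    def test_jitter_perturbs_active_templates_only(self):
        subj = mg.make_subject(5)
        sess = mg.session_variant(subj, 9)
        assert not np.array_equal(
            sess.templates[1].amplitude_map, subj.templates[1].amplitude_map
        )
        assert sess.templates[syn.NEUTRAL_LABEL].amplitude_map.max() == 0.0

    def test_column_shift_rolls_grid(self):
        subj = mg.make_subject(5)
        sess = mg.session_variant(subj, 9, column_shift=1)
        unshifted = mg.session_variant(subj, 9, column_shift=0)
        np.testing.assert_allclose(
            sess.templates[1].amplitude_map,
            np.roll(unshifted.templates[1].amplitude_map, 1, axis=1),
        )
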