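import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mstates as ms
from mstates.backfit import MicrostateSequence, SmoothingConfig


def rec_from(data, rate=100.0):
    mont = ms.ChannelMontage(tuple(f"c{i}" for i in range(data.shape[0])))
    return ms.EEGRecording(data=np.asarray(data, float), rate=rate, montage=mont)


class TestAssignLabels:
    def test_scaled_template(self, wrap_templates):
        templates = ms.make_templates(8, 3, seed=1)
        data = np.tile(5.0 * templates[1][:, None], (1, 10))
        seq = ms.assign_labels(rec_from(data), wrap_templates(templates))
        assert np.all(seq.labels == 2)

    def test_polarity_absorbed(self, wrap_templates):
        templates = ms.make_templates(8, 3, seed=1)
        data = -templates[0][:, None]
        seq = ms.assign_labels(rec_from(data), wrap_templates(templates), "invariant")
        assert seq.labels[0] == 1

    def test_ground_truth_recovered_noise_free(self, wrap_templates):
        cfg = ms.SynthConfig(K=4, length=4.0, snr=1e9, seed=11)
        rec, truth = ms.simulate(cfg)
        seq = ms.assign_labels(ms.average_reference(rec), wrap_templates(truth.templates))
        assert np.array_equal(seq.labels, truth.labels.labels)

    def test_channel_mismatch(self, wrap_templates, rng):
        templates = ms.make_templates(8, 3, seed=1)
        with pytest.raises(ValueError):
            ms.assign_labels(rec_from(rng.normal(size=(6, 5))), wrap_templates(templates))


class TestSmoothLabels:
    def test_short_run_absorbed(self, wrap_templates):
        templates = ms.make_templates(8, 2, seed=2)
        # columns follow A A B A A but the 'B' sample is actually closer to A
        cols = [templates[0]] * 2 + [templates[0] * 0.9 + templates[1] * 0.3] + [templates[0]] * 2
        rec = rec_from(np.array(cols).T)
        seq = MicrostateSequence(np.array([1, 1, 2, 1, 1]), 2, 100.0)
        out = ms.smooth_labels(seq, SmoothingConfig(min_duration=2), rec, wrap_templates(templates))
        assert out.labels.tolist() == [1, 1, 1, 1, 1]

    def test_long_runs_untouched(self, wrap_templates, rng):
        templates = ms.make_templates(8, 2, seed=2)
        labels = np.repeat([1, 2, 1], 5)
        rec = rec_from(rng.normal(size=(8, len(labels))))
        seq = MicrostateSequence(labels, 2, 100.0)
        out = ms.smooth_labels(seq, SmoothingConfig(min_duration=3), rec, wrap_templates(templates))
        assert np.array_equal(out.labels, labels)

    def test_single_class_unchanged(self, wrap_templates, rng):
        templates = ms.make_templates(8, 2, seed=2)
        labels = np.ones(20, dtype=int)
        rec = rec_from(rng.normal(size=(8, 20)))
        out = ms.smooth_labels(
            MicrostateSequence(labels, 2, 100.0),
            SmoothingConfig(min_duration=3),
            rec,
            wrap_templates(templates),
        )
        assert np.array_equal(out.labels, labels)

    def test_no_foreign_labels_introduced(self, wrap_templates, rng):
        templates = ms.make_templates(8, 4, seed=5)
        labels = rng.integers(1, 5, 60)
        rec = rec_from(rng.normal(size=(8, 60)))
        out = ms.smooth_labels(
            MicrostateSequence(labels, 4, 100.0),
            SmoothingConfig(min_duration=3),
            rec,
            wrap_templates(templates),
        )
        assert set(np.unique(out.labels)) <= {1, 2, 3, 4}

    def test_min_duration_enforced_on_backfit_output(self, wrap_templates):
        cfg = ms.SynthConfig(K=4, length=8.0, snr=2.0, seed=31)
        rec, truth = ms.simulate(cfg)
        rec = ms.average_reference(rec)
        ts = wrap_templates(truth.templates)
        seq = ms.assign_labels(rec, ts)
        out = ms.smooth_labels(seq, SmoothingConfig(min_duration=3), rec, ts)
        runs = ms.extract_segments(out).runs
        interior = runs[1:-1]
        if len(interior):
            assert interior[:, 2].min() >= 3


class TestExtractSegments:
    def test_example(self):
        seq = MicrostateSequence(np.array([1, 1, 2, 2, 2, 1]), 2, 10.0)
        runs = ms.extract_segments(seq).runs
        assert runs.tolist() == [[1, 0, 2], [2, 2, 3], [1, 5, 1]]

    def test_constant(self):
        seq = MicrostateSequence(np.ones(7, dtype=int), 1, 10.0)
        runs = ms.extract_segments(seq).runs
        assert runs.tolist() == [[1, 0, 7]]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 3), min_size=1, max_size=40))
    def test_round_trip(self, labels):
        seq = MicrostateSequence(np.array(labels), 3, 10.0)
        segs = ms.extract_segments(seq)
        assert segs.decode().tolist() == labels
        assert segs.runs[:, 2].sum() == len(labels)  # conservation


class TestPeakOnlyLabeling:
    def test_nearest_peak_interpolation(self, wrap_templates):
        templates = ms.make_templates(8, 2, seed=6)
        # samples 0-2 look like class 1, samples 3-5 like class 2
        cols = [templates[0]] * 3 + [templates[1]] * 3
        rec = rec_from(np.array(cols).T)
        seq = ms.assign_labels(rec, wrap_templates(templates), at_peaks=np.array([1, 4]))
        assert seq.labels.tolist() == [1, 1, 1, 2, 2, 2]
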