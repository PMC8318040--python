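import itertools

import numpy as np
import pytest

import mstates as ms
from mstates.backfit import MicrostateSequence
from mstates.features import feature_names, temporal_features, transition_matrix


def seq_of(labels, K=3, rate=100.0):
    return MicrostateSequence(np.array(labels, dtype=int), K, rate)


def segs_of(labels, K=3, rate=100.0):
    return ms.extract_segments(seq_of(labels, K, rate))


class TestTemporalParameters:
    def test_mean_duration_single_run(self):
        segs = segs_of([1] * 50, K=1, rate=500.0)
        assert ms.mean_duration(segs, 1, 500.0) == pytest.approx(100.0)

    def test_mean_duration_two_runs(self):
        segs = segs_of([1] * 10 + [2] * 5 + [1] * 30, rate=100.0)
        assert ms.mean_duration(segs, 1, 100.0) == pytest.approx(200.0)

    def test_absent_class_zero(self):
        segs = segs_of([1, 1, 1])
        assert ms.mean_duration(segs, 3, 100.0) == 0.0
        assert ms.occurrence(segs, 3, 100.0) == 0.0
        assert ms.coverage(segs, 3) == 0.0

    def test_occurrence(self):
        labels = ([1] * 100 + [2] * 150) * 4  # 4 runs of class 1 in 10 s at 100 Hz
        segs = segs_of(labels, rate=100.0)
        assert ms.occurrence(segs, 1, 100.0) == pytest.approx(0.4)

    def test_occurrence_single_covering_run(self):
        segs = segs_of([1] * 500, K=1, rate=100.0)  # 5-s window
        assert ms.occurrence(segs, 1, 100.0) == pytest.approx(0.2)

    def test_coverage_half(self):
        segs = segs_of([1] * 25 + [2] * 25)
        assert ms.coverage(segs, 1) == pytest.approx(50.0)

    def test_coverage_partition(self, rng):
        labels = rng.integers(1, 4, 200)
        segs = segs_of(labels)
        assert sum(ms.coverage(segs, c) for c in (1, 2, 3)) == pytest.approx(100.0)

    def test_identity_on_random_sequences(self, rng):
        # coverage = occurrence * duration / 10, exactly, for every class
        for _ in range(200):
            labels = rng.integers(1, 5, int(rng.integers(2, 120)))
            segs = segs_of(labels, K=4, rate=250.0)
            for c in range(1, 5):
                cov = ms.coverage(segs, c)
                occ = ms.occurrence(segs, c, 250.0)
                dur = ms.mean_duration(segs, c, 250.0)
                assert cov == pytest.approx(occ * dur / 10.0, abs=1e-9)


class TestClassGEV:
    def test_noise_free_sums_to_100(self, wrap_templates):
        cfg = ms.SynthConfig(K=4, length=3.0, snr=1e9, seed=4)
        rec, truth = ms.simulate(cfg)
        gevs = ms.class_gev(
            truth.labels, ms.average_reference(rec), wrap_templates(truth.templates)
        )
        assert gevs.sum() == pytest.approx(100.0, abs=0.01)

    def test_orthogonal_recording_zero(self, wrap_templates):
        basis = ms.make_templates(8, 4, seed=9)  # mutually orthogonal rows
        templates, extra = basis[:3], basis[3]
        mont = ms.ChannelMontage(tuple(f"c{i}" for i in range(8)))
        rec = ms.EEGRecording(
            data=np.tile(extra[:, None], (1, 10)), rate=100.0, montage=mont
        )
        seq = seq_of([1] * 10, K=3)
        gevs = ms.class_gev(seq, rec, wrap_templates(templates))
        assert np.all(gevs < 1e-6)

    def test_matches_brute_force(self, wrap_templates, rng):
        # 3-sample toy vs direct summation of the GFP^2-weighted formula
        templates = ms.make_templates(6, 2, seed=3)
        data = rng.normal(size=(6, 3))
        mont = ms.ChannelMontage(tuple(f"c{i}" for i in range(6)))
        rec = ms.EEGRecording(data=data, rate=10.0, montage=mont)
        seq = seq_of([1, 2, 1], K=2, rate=10.0)
        gevs = ms.class_gev(seq, rec, wrap_templates(templates))

        X = data - data.mean(axis=0, keepdims=True)
        gfp = X.std(axis=0)
        denom = (gfp**2).sum()
        expected = np.zeros(2)
        for t, l in enumerate([1, 2, 1]):
            c = ms.spatial_correlation(X[:, t], templates[l - 1])
            expected[l - 1] += gfp[t] ** 2 * c**2 / denom
        np.testing.assert_allclose(gevs, 100.0 * expected, atol=1e-9)


def hand_count_transitions(labels, K):
    counts = np.zeros((K, K))
    runs = [k for k, _ in itertools.groupby(labels)]
    for a, b in zip(runs[:-1], runs[1:]):
        counts[a - 1, b - 1] += 1
    probs = np.zeros_like(counts)
    for i in range(K):
        if counts[i].sum():
            probs[i] = counts[i] / counts[i].sum()
    return probs


class TestTransitionMatrix:
    def test_hand_enumeration(self):
        # runs A B A C: A->B, B->A, A->C
        tm = transition_matrix(segs_of([1, 2, 1, 3]), 3)
        assert tm.probs[0, 1] == pytest.approx(0.5)
        assert tm.probs[0, 2] == pytest.approx(0.5)
        assert tm.probs[1, 0] == pytest.approx(1.0)
        assert np.all(tm.probs[2] == 0.0)

    def test_single_run_all_zero(self):
        tm = transition_matrix(segs_of([1, 1, 1]), 3)
        assert np.all(tm.probs == 0.0)

    def test_alternating(self):
        tm = transition_matrix(segs_of([1, 2] * 5, K=2), 2)
        assert tm.probs[0, 1] == pytest.approx(1.0)
        assert tm.probs[1, 0] == pytest.approx(1.0)

    def test_exhaustive_three_class_short_sequences(self):
        # every 3-class sequence of length <= 5 against the hand-count oracle
        for n in range(1, 6):
            for labels in itertools.product([1, 2, 3], repeat=n):
                tm = transition_matrix(segs_of(list(labels)), 3)
                np.testing.assert_allclose(
                    tm.probs, hand_count_transitions(labels, 3), atol=1e-12
                )

    def test_rows_stochastic(self, rng):
        labels = rng.integers(1, 5, 300)
        tm = transition_matrix(segs_of(labels, K=4), 4)
        sums = tm.probs.sum(axis=1)
        for i in range(4):
            assert sums[i] == pytest.approx(1.0) or sums[i] == 0.0
        assert np.all(np.diag(tm.probs) == 0.0)

    def test_sample_level_mode(self):
        tm = transition_matrix(seq_of([1, 1, 2]), 2, level="sample")
        # pairs: (1,1), (1,2)
        assert tm.probs[0, 0] == pytest.approx(0.5)
        assert tm.probs[0, 1] == pytest.approx(0.5)


class TestSplitWindows:
    def make_rec(self, seconds, rate=100.0):
        mont = ms.ChannelMontage(("a", "b"))
        n = int(seconds * rate)
        return ms.EEGRecording(
            data=np.arange(2 * n, dtype=float).reshape(2, n), rate=rate, montage=mont
        )

    def test_sixty_seconds_twelve_windows(self):
        assert len(ms.split_windows(self.make_rec(60.0), 5.0)) == 12

    def test_remainder_dropped(self):
        wins = ms.split_windows(self.make_rec(7.0), 5.0)
        assert len(wins) == 1
        assert wins[0].n_samples == 500

    def test_disjoint_and_ordered(self):
        wins = ms.split_windows(self.make_rec(15.0), 5.0)
        starts = [w.meta["window_start"] for w in wins]
        assert starts == [0, 500, 1000]

    def test_too_short(self):
        with pytest.raises(ValueError):
            ms.split_windows(self.make_rec(2.0), 5.0)


class TestFeatureVector:
    def build(self, K, rng):
        labels = rng.integers(1, K + 1, 400)
        seq = seq_of(labels, K=K)
        tf = temporal_features(seq)
        tm = transition_matrix(ms.extract_segments(seq), K)
        return tf.fillna(0.0), tm

    def test_lengths(self, rng):
        tf, tm = self.build(9, rng)
        assert len(ms.build_feature_vector(tf, tm, "combined")) == 108
        tf, tm = self.build(10, rng)
        assert len(ms.build_feature_vector(tf, tm, "transitions")) == 90
        assert len(feature_names(9, "combined")) == 108

    def test_deterministic(self, rng):
        tf, tm = self.build(4, rng)
        v1 = ms.build_feature_vector(tf, tm)
        v2 = ms.build_feature_vector(tf, tm)
        np.testing.assert_array_equal(v1, v2)

    def test_permutation_equivariant(self, rng):
        K = 3
        labels = rng.integers(1, K + 1, 300)
        perm = {1: 2, 2: 3, 3: 1}
        seq_a = seq_of(labels, K=K)
        seq_b = seq_of([perm[l] for l in labels], K=K)
        va = ms.build_feature_vector(
            temporal_features(seq_a).fillna(0),
            transition_matrix(ms.extract_segments(seq_a), K),
        )
        vb = ms.build_feature_vector(
            temporal_features(seq_b).fillna(0),
            transition_matrix(ms.extract_segments(seq_b), K),
        )
        names_a = feature_names(K)
        names_b = feature_names(K)
        fa = dict(zip(names_a, va))
        fb = dict(zip(names_b, vb))
        for stem in ("dur_ms", "occ", "cov", "gev"):
            for c in (1, 2, 3):
                assert fa[f"{stem}.c{c}"] == pytest.approx(fb[f"{stem}.c{perm[c]}"])
        for i, j in itertools.permutations((1, 2, 3), 2):
            assert fa[f"tp.c{i}.c{j}"] == pytest.approx(fb[f"tp.c{perm[i]}.c{perm[j]}"])

    def test_k_mismatch(self, rng):
        tf, _ = self.build(3, rng)
        _, tm = self.build(4, rng)
        with pytest.raises(ValueError):
            ms.build_feature_vector(tf, tm)
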