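import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mstates as ms
from mstates.cluster import ClusteringConfig, centroid, dtaahc, gev, gmd
from mstates.gfp import TopographyMatrix


def topo_matrix(maps, gfp=None):
    maps = np.atleast_2d(np.asarray(maps, float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    if gfp is None:
        gfp = np.sqrt(np.mean(maps**2, axis=1))
    return TopographyMatrix(
        maps=maps,
        gfp=np.asarray(gfp, float),
        origin=pd.DataFrame({"recording_id": 0, "sample": range(len(maps))}),
    )


M = np.array([1.0, -2.0, 3.0, -2.0])


class TestSpatialCorrelation:
    def test_self(self):
        assert ms.spatial_correlation(M, M) == pytest.approx(1.0)

    def test_inverted(self):
        assert ms.spatial_correlation(M, -M) == pytest.approx(-1.0)

    def test_orthogonal(self):
        assert ms.spatial_correlation(
            np.array([1.0, -1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0, -1.0])
        ) == pytest.approx(0.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            ms.spatial_correlation(np.zeros(4), M)


class TestGMD:
    def test_homogeneity(self):
        assert gmd(M, M) == pytest.approx(0.0)

    def test_inversion(self):
        assert gmd(M, -M) == pytest.approx(2.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0, -1.0])
        assert gmd(u, v) == pytest.approx(np.sqrt(2.0))

    def test_symmetry_and_sign(self, rng):
        for _ in range(25):
            u, v = rng.normal(size=(2, 8))
            assert gmd(u, v) == pytest.approx(gmd(v, u))
            assert gmd(u, v) == pytest.approx(gmd(-u, -v))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_relation_to_correlation(self, seed):
        # for zero-mean maps: GMD^2 = 2 (1 - C)
        r = np.random.default_rng(seed)
        u, v = r.normal(size=(2, 12))
        u -= u.mean()
        v -= v.mean()
        c = ms.spatial_correlation(u, v)
        assert gmd(u, v) ** 2 == pytest.approx(2.0 * (1.0 - c), abs=1e-9)


class TestPolarityDissimilarity:
    def test_invariant_absorbs_flip(self):
        assert ms.polarity_dissimilarity(M, -M, "invariant") == pytest.approx(0.0)

    def test_signed_keeps_flip(self):
        assert ms.polarity_dissimilarity(M, -M, "signed") == pytest.approx(2.0)

    def test_invariant_never_exceeds_signed(self, rng):
        for _ in range(100):
            u, v = rng.normal(size=(2, 10))
            assert ms.polarity_dissimilarity(u, v, "invariant") <= ms.polarity_dissimilarity(
                u, v, "signed"
            ) + 1e-12


def naive_gev(maps, templates, labels):
    """Two-loop reference implementation of GFP^2-weighted explained variance."""
    w = maps.gfp**2
    denom = w.sum()
    K = templates.shape[0]
    per = np.zeros(K)
    for l in range(1, K + 1):
        for t in range(maps.n_maps):
            if labels[t] == l:
                c = ms.spatial_correlation(maps.maps[t], templates[l - 1])
                per[l - 1] += w[t] * c**2 / denom
    return per, per.sum()


class TestGEV:
    def test_all_maps_equal_template(self):
        maps = topo_matrix(np.vstack([M * s for s in (1.0, 2.0, 0.5)]))
        per, total = gev(maps, M[None, :], np.array([1, 1, 1]))
        assert total == pytest.approx(1.0)

    def test_orthogonal_class_zero(self):
        u = np.array([1.0, -1.0, 0.0, 0.0])
        v = np.array([0.0, 0.0, 1.0, -1.0])
        maps = topo_matrix(np.vstack([v, v]))
        per, total = gev(maps, u[None, :], np.array([1, 1]))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_half(self):
        # maps with GFP {1, 2, 1} and correlations {1, 0.5, 1} to one class:
        # GEV = (1 + 4*0.25 + 1) / 6 = 0.5
        m = M / np.sqrt(np.mean(M**2))
        orth = np.array([1.0, 1.0, 0.0, -2.0])
        orth -= orth.mean()
        orth -= m * np.dot(orth, m) / np.dot(m, m)
        o = orth / np.sqrt(np.mean(orth**2))
        v_half = 0.5 * m + np.sqrt(3.0) / 2.0 * o  # unit GFP, C = 0.5 with m
        maps = TopographyMatrix(
            maps=np.vstack([m, 2.0 * v_half, m]),
            gfp=np.array([1.0, 2.0, 1.0]),
            origin=pd.DataFrame({"recording_id": 0, "sample": [0, 1, 2]}),
        )
        _, total = gev(maps, m[None, :], np.array([1, 1, 1]))
        assert total == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_double_loop(self, rng):
        for trial in range(5):
            n, K, N = int(rng.integers(5, 50)), int(rng.integers(2, 5)), 8
            maps = topo_matrix(rng.normal(size=(n, N)), gfp=rng.uniform(0.5, 3.0, n))
            templates = rng.normal(size=(K, N))
            templates -= templates.mean(axis=1, keepdims=True)
            labels = rng.integers(1, K + 1, n)
            per, total = gev(maps, templates, labels)
            per_ref, total_ref = naive_gev(maps, templates, labels)
            np.testing.assert_allclose(per, per_ref, atol=1e-12)
            assert total == pytest.approx(total_ref, abs=1e-12)


class TestCentroid:
    def test_singleton(self):
        np.testing.assert_allclose(centroid(M[None, :]), M - M.mean())

    def test_duplicate(self):
        np.testing.assert_allclose(centroid(np.vstack([M, M])), M - M.mean())

    def test_invariant_antiparallel_pair(self):
        c = centroid(np.vstack([M, -M]), mode="invariant")
        m0 = M - M.mean()
        assert min(np.linalg.norm(c - m0), np.linalg.norm(c + m0)) < 1e-12

    def test_signed_antiparallel_degenerate(self):
        with pytest.raises(ValueError):
            centroid(np.vstack([M, -M]), mode="signed")


class TestDTAAHC:
    def make_planted(self, K, copies, rng, noise=0.0):
        templates = ms.make_templates(16, K, seed=int(rng.integers(2**16)))
        rows, labels = [], []
        for l in range(K):
            for _ in range(copies):
                sign = rng.choice([-1.0, 1.0])
                rows.append(sign * templates[l] + noise * rng.normal(size=16))
                labels.append(l + 1)
        return topo_matrix(np.vstack(rows)), templates, np.array(labels)

    def test_noise_free_three_classes(self, rng):
        maps, planted, _ = self.make_planted(3, 10, rng)
        ts = dtaahc(maps)
        assert ts.K == 3
        assert ts.total_gev == pytest.approx(1.0, abs=1e-9)
        matched = [
            min(ms.polarity_dissimilarity(t, p) for p in planted) for t in ts.templates
        ]
        assert max(matched) < 1e-6

    def test_all_identical_maps(self):
        maps = topo_matrix(np.vstack([M] * 6))
        ts = dtaahc(maps)
        assert ts.K == 1
        assert ts.total_gev == pytest.approx(1.0)

    def test_near_duplicates_merged(self, rng):
        base = ms.make_templates(16, 2, seed=3)
        # two planted maps with mutual dissimilarity ~0.05 (< th_gmd)
        near = base[0] + 0.035 * rng.normal(size=16)
        near -= near.mean()
        assert ms.polarity_dissimilarity(base[0], near) < 0.1
        rows = [base[0]] * 8 + [near] * 8 + [base[1]] * 8
        ts = dtaahc(topo_matrix(np.vstack(rows)))
        assert ts.K == 2

    def test_deterministic(self, rng):
        maps, _, _ = self.make_planted(4, 8, rng, noise=0.2)
        a = dtaahc(maps)
        b = dtaahc(maps)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.templates, b.templates)

    def test_template_set_invariants(self, rng):
        maps, _, _ = self.make_planted(5, 10, rng, noise=0.25)
        ts = dtaahc(maps)
        assert np.all(ts.per_class_gev >= 0)
        assert ts.per_class_gev.sum() == pytest.approx(ts.total_gev)
        assert ts.total_gev <= 1.0 + 1e-12
        np.testing.assert_allclose(ts.templates.mean(axis=1), 0.0, atol=1e-9)
        for i in range(ts.K):
            for j in range(i + 1, ts.K):
                assert (
                    ms.polarity_dissimilarity(ts.templates[i], ts.templates[j]) >= 0.1
                )
        # labels partition the training maps
        assert set(np.unique(ts.labels)) <= set(range(1, ts.K + 1))
        assert len(ts.labels) == maps.n_maps

    def test_terminates_on_random_input(self, rng):
        maps = topo_matrix(rng.normal(size=(200, 12)))
        ts = dtaahc(maps)  # must return, no non-termination
        assert 1 <= ts.K <= 200

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClusteringConfig(th_gev=1.5)
        with pytest.raises(ValueError):
            ClusteringConfig(th_gmd=2.5)
        with pytest.raises(ValueError):
            ClusteringConfig(polarity="other")


class TestTwoStage:
    def test_recovers_templates_across_subjects(self, rng):
        planted = ms.make_templates(16, 3, seed=44)
        subjects = []
        for s in range(3):
            rows = []
            for l in range(3):
                for _ in range(10):
                    sign = rng.choice([-1.0, 1.0])
                    rows.append(sign * planted[l] + 0.15 * rng.normal(size=16))
            subjects.append(topo_matrix(np.vstack(rows)))
        ts = ms.dtaahc_two_stage(subjects)
        assert ts.K == 3
        worst = max(
            min(ms.polarity_dissimilarity(t, p) for p in planted) for t in ts.templates
        )
        assert worst < 0.1
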