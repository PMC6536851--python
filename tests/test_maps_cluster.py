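"""GFP, peak detection, spatial correlation, TAAHC (with a brute-force
partition oracle), GEV, meta-criterion k selection, and group map averaging."""

import itertools

import numpy as np
import pytest

from microdyn import (
    TAAHCClustering,
    compute_gfp,
    find_gfp_peaks,
    gev,
    group_mean_maps,
    select_k_meta,
    spatial_correlation,
    taahc,
    unit_gfp,
)
from microdyn.cluster import _centroid


def random_maps(rng, n, c):
    m = rng.standard_normal((n, c))
    return m - m.mean(axis=1, keepdims=True)


class TestGFP:
    def test_zero_epoch(self):
        g = compute_gfp(np.zeros((4, 10)))
        assert np.all(g.values == 0) and g.n_peaks == 0

    def test_unit_spread_map(self):
        col = np.array([1.0, 1.0, -1.0, -1.0])
        epoch = np.tile(col[:, None], (1, 5))
        assert np.allclose(compute_gfp(epoch).values, 1.0)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        ep = random_maps(rng, 8, 50).T
        np.testing.assert_allclose(
            compute_gfp(-3.0 * ep).values, 3.0 * compute_gfp(ep).values
        )

    def test_requires_average_reference(self):
        with pytest.raises(ValueError, match="average-referenced"):
            compute_gfp(np.arange(40.0).reshape(4, 10) + 5)


class TestFindPeaks:
    def test_monotone_series_has_none(self):
        assert find_gfp_peaks(np.arange(10.0)).size == 0

    def test_plateau_takes_left_centre(self):
        np.testing.assert_array_equal(find_gfp_peaks(np.array([0, 1, 1, 0.0])), [1])

    def test_rectified_envelope_rate(self):
        t = np.arange(int(256 * 2)) / 256
        peaks = find_gfp_peaks(np.abs(np.sin(2 * np.pi * 10 * t)))
        assert 39 <= peaks.size <= 40  # two field-power maxima per cycle

    def test_endpoints_never_peaks(self):
        peaks = find_gfp_peaks(np.array([5.0, 1.0, 2.0, 1.0, 9.0]))
        np.testing.assert_array_equal(peaks, [2])


class TestSpatialCorrelation:
    def test_identity_negation_orthogonal(self):
        rng = np.random.default_rng(1)
        a = random_maps(rng, 1, 20)[0]
        assert spatial_correlation(a, a) == pytest.approx(1.0)
        assert spatial_correlation(a, -a, polarity_invariant=True) == pytest.approx(1.0)
        assert spatial_correlation(a, -a, polarity_invariant=False) == pytest.approx(-1.0)
        b = random_maps(rng, 1, 20)[0]
        b -= (b @ a) / (a @ a) * a  # orthogonalize (both centred)
        assert spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            spatial_correlation(np.zeros(5), np.arange(5.0))


def planted_maps(rng, k, per_cluster, c, noise=0.05):
    base = random_maps(rng, k, c)
    maps, truth = [], []
    for ci in range(k):
        for _ in range(per_cluster):
            m = base[ci] + noise * rng.standard_normal(c)
            maps.append(m - m.mean())
            truth.append(ci)
    return np.array(maps), np.array(truth)


def brute_force_best_partition(maps, k):
    """Exhaustive search of the GEV-optimal partition into exactly k blocks."""
    n = maps.shape[0]
    X = unit_gfp(maps)
    best_labels, best_gev = None, -1.0

    def partitions(idx, blocks):
        if not idx:
            if len(blocks) == k:
                yield blocks
            return
        head, rest = idx[0], idx[1:]
        for i in range(len(blocks)):
            yield from partitions(rest, blocks[:i] + [blocks[i] + [head]] + blocks[i + 1:])
        if len(blocks) < k:
            yield from partitions(rest, blocks + [[head]])

    for blocks in partitions(list(range(n)), []):
        labels = np.empty(n, dtype=int)
        templ = []
        for ci, b in enumerate(blocks):
            labels[np.array(b)] = ci
            templ.append(_centroid(X[np.array(b)], True))
        g = gev(np.array(templ), maps, labels=labels)
        if g > best_gev:
            best_gev, best_labels = g, labels
    return best_labels, best_gev


def same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


class TestTAAHC:
    def test_k_equals_n_maps_gives_gev_one(self):
        rng = np.random.default_rng(2)
        maps = random_maps(rng, 6, 16)
        sol = taahc(maps, 6, 6)[6]
        assert sol.gev == pytest.approx(1.0)

    def test_duplicate_maps_co_clustered(self):
        rng = np.random.default_rng(3)
        maps = random_maps(rng, 7, 16)
        maps[3] = maps[0]
        for k in range(2, 6):
            sol = taahc(maps, k, k)[k]
            assert sol.labels[0] == sol.labels[3]

    @pytest.mark.parametrize("instance", range(3))
    def test_matches_exhaustive_gev_optimum(self, instance):
        rng = np.random.default_rng(100 + instance)
        maps, truth = planted_maps(rng, 3, 3, 16)
        sol = taahc(maps, 3, 3)[3]
        assert same_partition(sol.labels, truth)
        brute_labels, brute_gev = brute_force_best_partition(maps, 3)
        assert same_partition(sol.labels, brute_labels)
        assert sol.gev == pytest.approx(brute_gev, abs=1e-12)

    def test_gev_nondecreasing_in_k(self):
        rng = np.random.default_rng(4)
        maps, _ = planted_maps(rng, 4, 10, 24, noise=0.5)
        sols = taahc(maps, 1, 8)
        gevs = [sols[k].gev for k in range(1, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(gevs, gevs[1:]))
        assert all(0.0 <= g <= 1.0 for g in gevs)

    def test_k_max_exceeding_maps_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            taahc(random_maps(rng, 5, 16), 1, 6)


class TestGEV:
    def test_exact_and_orthogonal(self):
        rng = np.random.default_rng(6)
        t = unit_gfp(random_maps(rng, 3, 20))
        assert gev(t, t) == pytest.approx(1.0)
        q, _ = np.linalg.qr(random_maps(rng, 20, 20).T)
        a, b = q[:, 0] - q[:, 0].mean(), q[:, 1] - q[:, 1].mean()
        b -= (b @ a) / (a @ a) * a
        assert gev(a[None, :], b[None, :]) < 1e-20

    def test_hand_computed_half(self):
        t = np.array([[1.0, -1.0, 1.0, -1.0]])
        orth = np.array([1.0, 1.0, -1.0, -1.0])
        maps = np.vstack([t[0], orth])
        # equal GFP, correlations 1 and 0 -> GEV = (1 + 0) / 2
        assert gev(t, maps) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            gev(np.ones((1, 4)), np.empty((0, 4)))


class TestSelectK:
    def test_identical_maps_return_k_min(self):
        maps = np.tile(np.array([1.0, -1.0, 2.0, -2.0]), (20, 1))
        sols = taahc(maps, 1, 5)
        assert select_k_meta(sols, maps) == 1

    @pytest.mark.parametrize("k_true", [3, 5])
    def test_planted_k_recovered(self, k_true):
        rng = np.random.default_rng(40 + k_true)
        maps, _ = planted_maps(rng, k_true, 40, 24, noise=0.1)
        sols = taahc(maps, 1, 10)
        assert select_k_meta(sols, maps) == k_true

    def test_single_criterion_raises(self):
        rng = np.random.default_rng(7)
        maps = random_maps(rng, 20, 16)
        sols = taahc(maps, 1, 5)
        with pytest.raises(ValueError):
            select_k_meta(sols, maps, criteria=("cv",))


class TestGroupMeanMaps:
    def test_identical_subjects_unchanged(self):
        rng = np.random.default_rng(8)
        t = unit_gfp(random_maps(rng, 4, 20))
        mean, perms = group_mean_maps([t, t, t])
        np.testing.assert_allclose(np.abs(np.sum(mean * t, axis=1)) / 20, 1.0,
                                   atol=1e-9)
        for p in perms:
            np.testing.assert_array_equal(p, np.arange(4))

    def test_label_shuffled_copies_recovered(self):
        rng = np.random.default_rng(9)
        t = unit_gfp(random_maps(rng, 4, 20))
        subs = [t[rng.permutation(4)] for _ in range(6)]
        mean, _ = group_mean_maps(subs)
        # every source class matched by exactly one mean map at |corr| = 1
        c = np.abs(np.corrcoef(np.vstack([mean, t]))[:4, 4:])
        assert np.allclose(np.sort(c.max(axis=0)), 1.0, atol=1e-9)
        assert np.allclose(np.sort(c.max(axis=1)), 1.0, atol=1e-9)

    def test_polarity_flipped_copies_recovered(self):
        rng = np.random.default_rng(10)
        t = unit_gfp(random_maps(rng, 3, 20))
        signs = [np.array(s, float) for s in ((1, -1, 1), (-1, 1, -1), (1, 1, -1))]
        subs = [t * s[:, None] for s in signs]
        mean, _ = group_mean_maps(subs)
        c = np.abs(np.corrcoef(np.vstack([mean, t]))[:3, 3:])
        assert np.allclose(c.max(axis=0), 1.0, atol=1e-9)

    def test_heterogeneous_k_raises(self):
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError):
            group_mean_maps([random_maps(rng, 3, 10), random_maps(rng, 4, 10)])


class TestEstimator:
    def test_sklearn_contract(self):
        rng = np.random.default_rng(12)
        maps, truth = planted_maps(rng, 3, 20, 16, noise=0.1)
        est = TAAHCClustering(n_clusters=3)
        labels = est.fit_predict(maps)
        assert same_partition(labels, truth)
        assert est.cluster_centers_.shape == (3, 16)
        assert est.get_params()["n_clusters"] == 3
        # predict is consistent with the training assignment on the same maps
        np.testing.assert_array_equal(est.predict(maps), est.labels_)
        # and noisy copies of training maps land in their source's cluster
        noisy = maps + 0.05 * rng.standard_normal(maps.shape)
        noisy -= noisy.mean(axis=1, keepdims=True)
        np.testing.assert_array_equal(est.predict(noisy), est.labels_)
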