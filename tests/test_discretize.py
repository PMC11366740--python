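"""DBSCAN clustering, dictionary construction and discrete encoding."""

import numpy as np
import pytest

from emomusic import discretize as dz


def _labels_equivalent(a, b):
    """Same partition up to cluster renumbering (noise label fixed)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def _random_instance(rng):
    n = int(rng.integers(5, 200))
    dim = int(rng.integers(2, 17))
    kind = rng.integers(3)
    if kind == 0:
        pts = rng.normal(size=(n, dim))
    elif kind == 1:  # blobs + outliers
        k = int(rng.integers(2, 5))
        centers = rng.normal(scale=10.0, size=(k, dim))
        pts = np.concatenate([
            centers[i] + rng.normal(scale=0.5, size=(max(n // k, 1), dim))
            for i in range(k)])
    else:            # duplicated points stress ties
        base = rng.normal(size=(max(n // 3, 2), dim))
        pts = base[rng.integers(0, base.shape[0], n)]
    eps = float(rng.uniform(0.3, 3.0))
    min_pts = int(rng.integers(1, 10))
    return pts, dz.DBSCANParams(eps, min_pts)


class TestEpsilonNeighborhood:
    def test_line_example(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        nb = dz.epsilon_neighborhood(pts, 0, dz.DBSCANParams(2.0, 1))
        assert set(nb.tolist()) == {0, 1}

    def test_isolation(self):
        pts = np.array([[0.0], [5.0], [10.0]])
        nb = dz.epsilon_neighborhood(pts, 1, dz.DBSCANParams(1.0, 1))
        assert set(nb.tolist()) == {1}

    def test_identical_points_full_set(self):
        pts = np.zeros((7, 3))
        nb = dz.epsilon_neighborhood(pts, 2, dz.DBSCANParams(1e-9, 1))
        assert nb.size == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dz.epsilon_neighborhood(np.empty((0, 2)), 0, dz.DBSCANParams(1.0, 1))


class TestDBSCAN:
    def test_two_blobs_no_noise(self):
        rng = np.random.default_rng(0)
        a = rng.normal(scale=0.3, size=(20, 2))
        b = np.array([10.0, 0.0]) + rng.normal(scale=0.3, size=(20, 2))
        pts = np.concatenate([a, b])
        out = dz.dbscan(pts, dz.DBSCANParams(1.5, 4))
        assert out.n_clusters == 2
        assert out.noise_fraction == 0.0
        assert len(set(out.labels[:20])) == 1
        assert len(set(out.labels[20:])) == 1

    def test_minpts_one_gives_connected_components(self):
        pts = np.array([[0.0], [0.5], [1.0], [5.0], [5.4]])
        out = dz.dbscan(pts, dz.DBSCANParams(0.6, 1))
        assert out.n_clusters == 2
        assert np.all(out.labels >= 0)

    def test_far_outlier_is_noise(self):
        rng = np.random.default_rng(1)
        blob = rng.normal(scale=0.2, size=(30, 2))
        pts = np.concatenate([blob, [[100.0, 100.0]]])
        out = dz.dbscan(pts, dz.DBSCANParams(1.0, 4))
        assert out.labels[-1] == -1

    def test_matches_reference_implementation_on_random_instances(self):
        """Label-partition equality with sklearn's DBSCAN (independent
        reference) over random instances up to 200 points."""
        from sklearn.cluster import DBSCAN as SkDBSCAN
        rng = np.random.default_rng(42)
        for _ in range(100):
            pts, params = _random_instance(rng)
            ours = dz.dbscan(pts, params)
            ref = SkDBSCAN(eps=params.epsilon, min_samples=params.min_pts,
                           metric="euclidean").fit(pts)
            assert _labels_equivalent(ours.labels, ref.labels_)

    def test_noise_fraction_monotone_in_epsilon(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(120, 3))
        fracs = [dz.dbscan(pts, dz.DBSCANParams(e, 4)).noise_fraction
                 for e in (0.2, 0.5, 0.8, 1.2, 2.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestDictionary:
    def _blobs(self, sizes, rng, spread=0.2, dim=2):
        centers = rng.normal(scale=20.0, size=(len(sizes), dim))
        pts, labels = [], []
        for i, s in enumerate(sizes):
            pts.append(centers[i] + rng.normal(scale=spread, size=(s, dim)))
            labels += [i] * s
        return np.concatenate(pts), np.array(labels)

    def test_centroid_is_member_mean(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        assign = dz.ClusterAssignment(np.array([0, 0]), 1)
        d = dz.build_dictionary(pts, assign, "eeg", dz.DBSCANParams(5.0, 1))
        np.testing.assert_allclose(d.centroids[0], [1.0, 0.0])

    def test_entries_ordered_by_size(self):
        rng = np.random.default_rng(3)
        pts, labels = self._blobs([10, 30], rng)
        assign = dz.ClusterAssignment(labels, 2)
        d = dz.build_dictionary(pts, assign, "eeg", dz.DBSCANParams(1.0, 4))
        # entry 0 must be the size-30 cluster
        np.testing.assert_allclose(d.centroids[0], pts[labels == 1].mean(axis=0),
                                   atol=1e-9)

    def test_representatives_are_nearest_members(self):
        rng = np.random.default_rng(4)
        pts, labels = self._blobs([20], rng)
        assign = dz.ClusterAssignment(labels, 1)
        d = dz.build_dictionary(pts, assign, "eeg", dz.DBSCANParams(1.0, 4),
                                n_representatives=3)
        centroid = pts.mean(axis=0)
        dists = np.linalg.norm(pts - centroid, axis=1)
        expected = pts[np.argsort(dists)[:3]]
        np.testing.assert_allclose(np.sort(d.representatives[0], axis=0),
                                   np.sort(expected, axis=0))

    def test_empty_dictionary_rejected(self):
        assign = dz.ClusterAssignment(np.array([-1, -1]), 0)
        with pytest.raises(dz.EmptyDictionaryError):
            dz.build_dictionary(np.zeros((2, 2)), assign, "eeg",
                                dz.DBSCANParams(0.1, 5))


class TestEncoding:
    def _dict(self, rng, k=5, dim=3):
        pts, labels = [], []
        centers = rng.normal(scale=10.0, size=(k, dim))
        for i in range(k):
            pts.append(centers[i] + rng.normal(scale=0.1, size=(30 - i, dim)))
            labels += [i] * (30 - i)
        frames = np.concatenate(pts)
        return dz.fit_dictionary(frames, "eeg"), frames

    def test_centroid_encodes_to_own_id(self, rng):
        d, _ = self._dict(rng)
        out = dz.encode_sequence(d.raw_centroids, d)
        np.testing.assert_array_equal(out.ids, np.arange(d.n_entries))

    def test_far_frame_is_unk(self, rng):
        d, frames = self._dict(rng)
        far = frames.mean(axis=0) + 1e6
        out = dz.encode_sequence(far[None, :], d)
        assert out.ids[0] == d.unk_id

    def test_matches_nearest_centroid_scan(self, rng):
        d, _ = self._dict(rng)
        frames = rng.normal(scale=10.0, size=(200, 3))
        out = dz.encode_sequence(frames, d, noise_factor=np.inf)
        z = d.zscore(frames)
        expected = np.linalg.norm(z[:, None, :] - d.centroids[None], axis=2
                                  ).argmin(axis=1)
        np.testing.assert_array_equal(out.ids, expected)

    def test_dimension_mismatch_rejected(self, rng):
        d, _ = self._dict(rng)
        with pytest.raises(ValueError):
            dz.encode_sequence(np.zeros((4, 7)), d)


class TestPersistence:
    def test_round_trip(self, rng, tmp_path):
        frames = rng.normal(size=(80, 4)) + np.repeat(
            np.arange(4)[:, None] * 20, 20, axis=0)
        d = dz.fit_dictionary(frames, "audio")
        path = dz.save_dictionary(d, tmp_path / "d.json")
        d2 = dz.load_dictionary(path)
        np.testing.assert_allclose(d.centroids, d2.centroids)
        np.testing.assert_allclose(d.scale_mean, d2.scale_mean)
        assert d.params == d2.params
        assert d.modality == d2.modality
        for r1, r2 in zip(d.representatives, d2.representatives):
            np.testing.assert_allclose(r1, r2)

    def test_truncated_file_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format_version": 1, "modality": "audio"')
        with pytest.raises(dz.DictionaryFormatError):
            dz.load_dictionary(p)

    def test_wrong_version_rejected(self, tmp_path):
        p = tmp_path / "v9.json"
        p.write_text('{"format_version": 9}')
        with pytest.raises(dz.DictionaryFormatError):
            dz.load_dictionary(p)
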