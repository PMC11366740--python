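"""DBSCAN discretization: cluster feature frames into a token dictionary.

Continuous per-window features (EEG differential entropy, audio MFCC)
are grouped with density-based clustering; each cluster's centroid and
a few representative members form one dictionary entry, and new frames
are encoded as the ID of the nearest centroid (or a reserved ``unk``
token when no centroid is close).  This turns both modalities into
discrete vocabularies over which the sequence model predicts.

Clustering follows the classic DBSCAN procedure: a point whose
epsilon-neighbourhood holds at least ``min_pts`` points (itself
included) is a core point; clusters are the maximal density-connected
sets grown from core points; border points join the first cluster that
reaches them; everything else is noise (label -1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

FORMAT_VERSION = 1


class EmptyDictionaryError(ValueError):
    """No clusters found; epsilon / min_pts need adjusting."""


class DictionaryFormatError(ValueError):
    pass


@dataclass(frozen=True)
class DBSCANParams:
    epsilon: float
    min_pts: int
    metric: str = "euclidean"

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ClusterAssignment:
    labels: np.ndarray          # -1 = noise
    n_clusters: int

    @property
    def noise_fraction(self) -> float:
        return float(np.mean(self.labels == -1))


@dataclass
class FeatureDictionary:
    """Ordered discrete vocabulary of (centroid, representatives) entries.

    Entries are ordered by descending cluster size (ties: first-seen
    frame index), so IDs are stable across runs.  ``scale_mean`` /
    ``scale_std`` record the z-scoring applied before clustering and are
    re-applied when encoding new frames.  ``unk_id`` (== ``len(entries)``)
    is the reserved token for frames no centroid explains.
    """

    centroids: np.ndarray                    # n_entries x dim (z-scored space)
    representatives: list[np.ndarray]        # per entry: R x dim
    modality: str                            # "eeg" | "audio"
    params: DBSCANParams
    scale_mean: np.ndarray
    scale_std: np.ndarray
    raw_centroids: np.ndarray = None         # centroids in original units

    def __post_init__(self):
        if self.raw_centroids is None:
            self.raw_centroids = self.centroids * self.scale_std + self.scale_mean

    @property
    def n_entries(self) -> int:
        return self.centroids.shape[0]

    @property
    def unk_id(self) -> int:
        return self.n_entries

    @property
    def vocab_size(self) -> int:
        """Entries plus the unk token — the prediction-head size."""
        return self.n_entries + 1

    def zscore(self, frames: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(frames) - self.scale_mean) / self.scale_std


@dataclass
class DiscreteSequence:
    ids: np.ndarray
    source_frames: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.source_frames = np.asarray(self.source_frames, dtype=np.int64)
        if self.ids.shape != self.source_frames.shape:
            raise ValueError("ids / source_frames length mismatch")

    def __len__(self):
        return self.ids.size


def _distances(frames: np.ndarray, metric: str) -> np.ndarray:
    return cdist(frames, frames, metric=metric)


def epsilon_neighborhood(frames: np.ndarray, i: int,
                         params: DBSCANParams) -> np.ndarray:
    """Indices q with dist(frames[i], frames[q]) <= epsilon (i included)."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[0] == 0:
        raise ValueError("empty frame list")
    if not 0 <= i < frames.shape[0]:
        raise IndexError(i)
    d = cdist(frames[i:i + 1], frames, metric=params.metric)[0]
    return np.flatnonzero(d <= params.epsilon)


def dbscan(frames: np.ndarray, params: DBSCANParams) -> ClusterAssignment:
    """Density-based clustering with core/border/noise labelling.

    Points are visited in index order; each unvisited core point seeds a
    new cluster that is expanded breadth-first through the neighbourhoods
    of its core members.  Border points take the label of the first
    cluster that reaches them.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n = frames.shape[0]
    if n == 0:
        raise ValueError("empty frame list")
    dist = _distances(frames, params.metric)
    neighbors = [np.flatnonzero(dist[i] <= params.epsilon) for i in range(n)]
    core = np.array([len(nb) >= params.min_pts for nb in neighbors])
    labels = np.full(n, -1, dtype=np.int64)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        queue = [i]
        while queue:
            p = queue.pop(0)
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(q)
        cluster += 1
    return ClusterAssignment(labels, cluster)


def suggest_params(frames: np.ndarray, min_pts: int | None = None,
                   metric: str = "euclidean") -> DBSCANParams:
    """k-distance heuristic for (epsilon, min_pts) on z-scored features.

    ``min_pts`` defaults to ``max(4, min(2*dim, n//10))``.  Epsilon comes
    from the sorted min_pts-th nearest-neighbour distance curve: when the
    curve's upper tail shows a large relative jump (ratio > 1.5 between
    consecutive sorted values — the signature of a noise tail), epsilon
    is the value just below the jump, so the tail becomes noise;
    otherwise the data is treated as noise-free and epsilon is 1.2x the
    95th percentile, making (almost) every point a core point and
    clusters the epsilon-connected components.
    """
    frames = np.atleast_2d(frames)
    n, dim = frames.shape
    if min_pts is None:
        min_pts = int(max(4, min(2 * dim, n // 25)))
        min_pts = min(min_pts, max(1, n - 1))
    d = _distances(frames, metric)
    kth = np.sort(np.sort(d, axis=1)[:, min(min_pts, n - 1)])
    eps = 1.2 * float(np.quantile(kth, 0.95))
    tail = kth[n // 2:]
    if tail.size >= 2:
        prev, nxt = tail[:-1], tail[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(prev > 0, nxt / prev, 1.0)
        j = int(np.argmax(ratio))
        if ratio[j] > 1.5:
            eps = float(prev[j])
    if eps <= 0:
        eps = float(np.quantile(kth[kth > 0], 0.5)) if np.any(kth > 0) else 1.0
    return DBSCANParams(eps, min_pts, metric)


def build_dictionary(frames: np.ndarray, assign: ClusterAssignment,
                     modality: str, params: DBSCANParams,
                     n_representatives: int = 5,
                     scale_mean: np.ndarray | None = None,
                     scale_std: np.ndarray | None = None) -> FeatureDictionary:
    """One entry per cluster: mean centroid + nearest members.

    ``frames`` must be the (z-scored) array the assignment was computed
    from; ``scale_mean``/``scale_std`` record that scaling for later
    encoding (identity if omitted).
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if assign.n_clusters == 0:
        raise EmptyDictionaryError(
            "DBSCAN found no clusters; increase epsilon or lower min_pts")
    dim = frames.shape[1]
    if scale_mean is None:
        scale_mean = np.zeros(dim)
    if scale_std is None:
        scale_std = np.ones(dim)
    sizes, first_seen, members = [], [], []
    for c in range(assign.n_clusters):
        idx = np.flatnonzero(assign.labels == c)
        sizes.append(idx.size)
        first_seen.append(idx.min())
        members.append(idx)
    order = sorted(range(assign.n_clusters),
                   key=lambda c: (-sizes[c], first_seen[c]))
    centroids, reps = [], []
    for c in order:
        idx = members[c]
        centroid = frames[idx].mean(axis=0)
        d = np.linalg.norm(frames[idx] - centroid, axis=1)
        nearest = idx[np.argsort(d, kind="stable")[:n_representatives]]
        centroids.append(centroid)
        reps.append(frames[nearest].copy())
    return FeatureDictionary(np.stack(centroids), reps, modality, params,
                             np.asarray(scale_mean, dtype=np.float64),
                             np.asarray(scale_std, dtype=np.float64))


def fit_dictionary(raw_frames: np.ndarray, modality: str,
                   params: DBSCANParams | None = None,
                   n_representatives: int = 5) -> FeatureDictionary:
    """Z-score, cluster and build a dictionary in one call."""
    raw_frames = np.atleast_2d(np.asarray(raw_frames, dtype=np.float64))
    mean = raw_frames.mean(axis=0)
    std = raw_frames.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    z = (raw_frames - mean) / std
    if params is None:
        params = suggest_params(z)
    assign = dbscan(z, params)
    return build_dictionary(z, assign, modality, params, n_representatives,
                            scale_mean=mean, scale_std=std)


def encode_sequence(raw_frames: np.ndarray, dictionary: FeatureDictionary,
                    noise_factor: float = 1.5,
                    source_frames: np.ndarray | None = None) -> DiscreteSequence:
    """Map each frame to the nearest centroid's ID, or ``unk_id``.

    Frames farther than ``epsilon * noise_factor`` from every centroid
    take the reserved unk token; distance ties resolve to the lowest ID.
    """
    z = dictionary.zscore(np.asarray(raw_frames, dtype=np.float64))
    if z.shape[1] != dictionary.centroids.shape[1]:
        raise ValueError(
            f"frame dim {z.shape[1]} != dictionary dim "
            f"{dictionary.centroids.shape[1]}")
    d = cdist(z, dictionary.centroids, metric=dictionary.params.metric)
    ids = d.argmin(axis=1)              # argmin takes the lowest index on ties
    too_far = d.min(axis=1) > dictionary.params.epsilon * noise_factor
    ids = np.where(too_far, dictionary.unk_id, ids)
    if source_frames is None:
        source_frames = np.arange(z.shape[0])
    return DiscreteSequence(ids, source_frames)


def save_dictionary(dictionary: FeatureDictionary, path: str | Path) -> Path:
    """JSON serialisation (text-only, lossless via float lists)."""
    path = Path(path)
    doc = {
        "format_version": FORMAT_VERSION,
        "modality": dictionary.modality,
        "params": {"epsilon": dictionary.params.epsilon,
                   "min_pts": dictionary.params.min_pts,
                   "metric": dictionary.params.metric},
        "scale_mean": dictionary.scale_mean.tolist(),
        "scale_std": dictionary.scale_std.tolist(),
        "centroids": dictionary.centroids.tolist(),
        "representatives": [r.tolist() for r in dictionary.representatives],
    }
    path.write_text(json.dumps(doc))
    return path


def load_dictionary(path: str | Path) -> FeatureDictionary:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
        if doc.get("format_version") != FORMAT_VERSION:
            raise DictionaryFormatError(
                f"unsupported dictionary format: {doc.get('format_version')}")
        params = DBSCANParams(**doc["params"])
        return FeatureDictionary(
            np.array(doc["centroids"], dtype=np.float64),
            [np.array(r, dtype=np.float64) for r in doc["representatives"]],
            doc["modality"], params,
            np.array(doc["scale_mean"], dtype=np.float64),
            np.array(doc["scale_std"], dtype=np.float64))
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise DictionaryFormatError(f"cannot read dictionary {path}: {exc}") from exc
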