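"""Normalized-cut spectral clustering of the cross-correlation matrix.

Uses the Ng-Jordan-Weiss symmetric-normalization variant: the affinity
matrix W (negative correlations clipped to zero, zero diagonal) is
normalized as L = D^(-1/2) W D^(-1/2), the top-k eigenvectors are
row-normalized to the unit sphere, and k-means (k-means++ initialization,
100 restarts, fixed seed) partitions the embedded points.  No spatial
constraint is applied.

Returned labels are renumbered canonically: 1..k by decreasing cluster
size, ties broken by the smallest contained voxel index, so a clustering
is reproducible across runs and platforms up to eigen-solver sign flips
(which leave pairwise distances in the embedding unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from joblib import Parallel, delayed
from sklearn.cluster import KMeans

from .io import LabelVolume, SeedSet

__all__ = [
    "Parcellation",
    "affinity_from_correlation",
    "spectral_cluster",
    "cluster_solutions",
    "canonicalize_labels",
    "DEFAULT_N_RESTARTS",
]

DEFAULT_N_RESTARTS = 100


@dataclass
class Parcellation:
    """Assignment of seed voxels to labels 1..k on a voxel grid."""

    seed_set: SeedSet
    labels: np.ndarray  # (n,) int, values in 1..k
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if len(self.labels) != len(self.seed_set):
            raise ValueError("one label per seed voxel required")
        present = np.unique(self.labels)
        if present.min(initial=1) < 1 or present.max(initial=1) > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        if len(present) != self.k:
            raise ValueError(f"all {self.k} clusters must be non-empty")

    def to_volume(self) -> LabelVolume:
        data = np.zeros(self.seed_set.shape, dtype=np.int32)
        data[tuple(self.seed_set.coordinates.T)] = self.labels
        return LabelVolume(data, self.seed_set.affine)

    @classmethod
    def from_volume(cls, vol: LabelVolume, seed_set: SeedSet | None = None
                    ) -> "Parcellation":
        from .io import extract_seed_coordinates

        if seed_set is None:
            seed_set = extract_seed_coordinates(vol)
        labels = vol.data[tuple(seed_set.coordinates.T)]
        if (labels <= 0).any():
            raise ValueError("seed set contains unlabeled voxels")
        return cls(seed_set, labels, int(labels.max()))

    def relabeled(self, permutation: np.ndarray) -> "Parcellation":
        """Apply a label bijection: new label = permutation[old - 1]."""
        perm = np.asarray(permutation, dtype=np.int32)
        if sorted(perm) != list(range(1, self.k + 1)):
            raise ValueError("permutation must be a bijection of 1..k")
        return Parcellation(self.seed_set, perm[self.labels - 1], self.k)


def affinity_from_correlation(corr: np.ndarray) -> np.ndarray:
    """Non-negative affinity: negative correlations clipped to 0, zero diag.

    Clipping (rather than shifting) preserves zero affinity for
    anti-correlated profiles.
    """
    corr = np.asarray(corr, dtype=np.float64)
    w = np.clip(corr, 0.0, None)
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def canonicalize_labels(labels0: np.ndarray, k: int) -> np.ndarray:
    """Renumber arbitrary cluster ids to 1..k by decreasing size; ties go
    to the cluster containing the smallest voxel index."""
    labels0 = np.asarray(labels0)
    ids = np.unique(labels0)
    order = sorted(
        ids, key=lambda c: (-int((labels0 == c).sum()),
                            int(np.argmax(labels0 == c)))
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels0], dtype=np.int32)


def _embedding(w: np.ndarray, k: int) -> np.ndarray:
    d = w.sum(axis=1)
    d = np.where(d <= 0, 1e-12, d)
    inv_sqrt = 1.0 / np.sqrt(d)
    lap = inv_sqrt[:, None] * w * inv_sqrt[None, :]
    lap = (lap + lap.T) / 2.0
    n = w.shape[0]
    _, vecs = scipy.linalg.eigh(lap, subset_by_index=[n - k, n - 1])
    norms = np.linalg.norm(vecs, axis=1)
    nonzero = norms > 0
    vecs[nonzero] /= norms[nonzero, None]
    return vecs


def spectral_cluster(
    w: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> np.ndarray:
    """Cluster a symmetric non-negative affinity matrix into k groups.

    Returns canonical labels 1..k (see module docstring).  Deterministic
    given (w, k, seed).
    """
    w = np.asarray(w, dtype=np.float64)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of voxels n={n}")
    if (w < 0).any():
        raise ValueError("affinity must be non-negative")
    embed = _embedding(w, k)
    for attempt in range(10):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            random_state=(seed + 1000 * attempt) % (2**32),
        ).fit(embed)
        if len(np.unique(km.labels_)) == k:
            return canonicalize_labels(km.labels_, k)
    raise RuntimeError(f"k-means produced an empty cluster for k={k}")


def cluster_solutions(
    corr: np.ndarray,
    k_min: int = 2,
    k_max: int = 12,
    seed: int = 0,
    n_restarts: int = DEFAULT_N_RESTARTS,
    n_jobs: int = 1,
    seed_set: SeedSet | None = None,
) -> dict[int, np.ndarray | Parcellation]:
    """One clustering per k over the contiguous range [k_min, k_max].

    Per-k runs are independent, so the worker count never changes the
    result.  If ``seed_set`` is given, values are :class:`Parcellation`
    objects; otherwise plain label arrays.
    """
    n = corr.shape[0]
    if not 2 <= k_min <= k_max <= n:
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    w = affinity_from_correlation(corr)
    ks = list(range(k_min, k_max + 1))
    results = Parallel(n_jobs=n_jobs)(
        delayed(spectral_cluster)(w, k, seed=seed, n_restarts=n_restarts)
        for k in ks
    )
    out: dict[int, np.ndarray | Parcellation] = {}
    for k, labels in zip(ks, results):
        out[k] = Parcellation(seed_set, labels, k) if seed_set is not None else labels
    return out


def ncut_objective(w: np.ndarray, labels: np.ndarray) -> float:
    """Normalized-cut objective sum_c cut(C, V\\C) / assoc(C, V).

    Small-n reference used to compare partitions; clusters with zero
    association contribute 0 if also cut-free, else infinity.
    """
    w = np.asarray(w, dtype=np.float64)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        inside = labels == c
        assoc = w[inside, :].sum()
        cut = w[np.ix_(inside, ~inside)].sum()
        if assoc == 0:
            if cut > 0:
                return float("inf")
            continue
        total += cut / assoc
    return total
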