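"""Cross-subject probabilistic maps and the maximum probability map.

The probabilistic map of cluster c holds, at each voxel, the fraction of
all subjects that assigned the voxel to c (an inverse measure of
inter-individual variability).  The maximum probability map (MPM) labels
each voxel with its most probable cluster; exact ties are resolved by
averaging each tied cluster's probability over the 26 directly adjacent
voxels (dividing by 26 regardless of how many neighbors lie inside the
volume) and keeping the larger average, with residual ties going to the
smallest label.  A post-processing pass corrects noisy voxels whose label
disagrees with the strict majority of their labeled 6-connected
neighbors, iterated to convergence (at most 10 sweeps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import LabelVolume
from .parcellate import Parcellation

__all__ = [
    "ProbabilisticMapSet",
    "MaximumProbabilityMap",
    "probability_maps",
    "maximum_probability_map",
    "remove_noise_voxels",
]


@dataclass
class ProbabilisticMapSet:
    """Per-cluster frequency volumes: probs[c - 1] is cluster c's map."""

    probs: np.ndarray  # (k, X, Y, Z) float in [0, 1]
    affine: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4 or self.probs.shape[0] != self.k:
            raise ValueError("probs must have shape (k, X, Y, Z)")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class MaximumProbabilityMap:
    volume: LabelVolume
    tie_broken: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.int64)
    )  # voxels whose label needed the 26-neighbor tie-break
    n_iterations: int = 0  # sweeps used by noise correction


def probability_maps(
    parcellations: list[Parcellation], n_subjects: int | None = None
) -> ProbabilisticMapSet:
    """Frequency maps over all subjects (consistent labels assumed).

    The denominator is the total number of subjects, so per-voxel sums
    over clusters are at most 1, with equality exactly where every
    subject labels the voxel.
    """
    if not parcellations:
        raise ValueError("no parcellations given")
    if n_subjects is None:
        n_subjects = len(parcellations)
    k = max(p.k for p in parcellations)
    shape = parcellations[0].seed_set.shape
    affine = parcellations[0].seed_set.affine
    counts = np.zeros((k,) + tuple(shape), dtype=np.int64)
    for p in parcellations:
        vol = p.to_volume().data
        for c in range(1, k + 1):
            counts[c - 1] += vol == c
    return ProbabilisticMapSet(counts / float(n_subjects), affine, k)


def _neighbor_average_26(vol: np.ndarray) -> np.ndarray:
    """Mean of the 26 adjacent values, out-of-volume neighbors counting 0."""
    total = np.zeros_like(vol, dtype=np.float64)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                total += _shift(vol, (dx, dy, dz))
    return total / 26.0


def _shift(vol: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(vol)
    src, dst = [], []
    for o, n in zip(offset, vol.shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def maximum_probability_map(pm: ProbabilisticMapSet) -> MaximumProbabilityMap:
    """Argmax labeling of the probabilistic maps with 26-neighbor tie-break."""
    probs = pm.probs
    pmax = probs.max(axis=0)
    labels = (np.argmax(probs, axis=0) + 1).astype(np.int32)
    labels[pmax <= 0] = 0

    is_max = probs >= pmax[None] - 1e-12
    tie_voxels = np.argwhere((is_max.sum(axis=0) >= 2) & (pmax > 0))
    if len(tie_voxels):
        nb_avg = np.stack([_neighbor_average_26(probs[c]) for c in range(pm.k)])
        for x, y, z in tie_voxels:
            tied = np.flatnonzero(is_max[:, x, y, z])
            avgs = nb_avg[tied, x, y, z]
            # largest neighbor average wins; residual tie -> smallest label
            labels[x, y, z] = tied[int(np.argmax(avgs))] + 1
    return MaximumProbabilityMap(
        LabelVolume(labels, pm.affine), tie_broken=tie_voxels
    )


def remove_noise_voxels(
    mpm: MaximumProbabilityMap, max_iter: int = 10
) -> MaximumProbabilityMap:
    """Flip voxels disagreeing with the strict majority of their labeled
    6-neighbors; repeat until stable or ``max_iter`` sweeps.

    Background voxels never gain a label, ties leave the voxel unchanged,
    and no new label value can appear, so the operation is idempotent once
    converged.
    """
    labels = mpm.volume.data.copy()
    k = int(labels.max(initial=0))
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
               (0, 0, -1)]
    iterations = 0
    for _ in range(max_iter):
        counts = np.zeros((k,) + labels.shape, dtype=np.int16)
        for off in offsets:
            shifted = _shift(labels, off)
            for c in range(1, k + 1):
                counts[c - 1] += shifted == c
        n_labeled = counts.sum(axis=0)
        top = counts.max(axis=0)
        majority = (np.argmax(counts, axis=0) + 1).astype(np.int32)
        strict = 2 * top > n_labeled  # implies the top label is unique
        flip = (labels > 0) & strict & (majority != labels)
        if not flip.any():
            break
        labels[flip] = majority[flip]
        iterations += 1
    return MaximumProbabilityMap(
        LabelVolume(labels, mpm.volume.affine),
        tie_broken=mpm.tie_broken,
        n_iterations=iterations,
    )
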