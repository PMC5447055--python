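"""Cross-subject (and cross-hemisphere) label harmonization.

Spectral clustering numbers its clusters arbitrarily, so the same
anatomical subregion gets different labels in different subjects.  The
remedy: pool all subjects' parcellations into a group similarity matrix
(entry (i, j) = fraction of subjects giving voxels i and j the same
label, thresholded at 0.5 by default), cluster that matrix once to get a
group-level labeling scheme, and propagate the scheme back to every
subject with an optimal linear assignment on the cluster-overlap matrix
(Hungarian algorithm).  Relabeling only renames clusters -- the partition
itself is untouched.

For paired left/right regions the right hemisphere is first mirrored onto
the left grid and its labels matched to the left parcellation, so that
homologous subregions share a label before the group scheme is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment

from .parcellate import Parcellation, spectral_cluster

__all__ = [
    "coincidence_matrix",
    "group_scheme",
    "match_labels",
    "relabel_subjects",
    "harmonize_hemispheres",
    "mirror_x",
    "DEFAULT_GROUP_THRESHOLD",
]

DEFAULT_GROUP_THRESHOLD = 0.5


def _label_matrix(parcellations: list[Parcellation]) -> np.ndarray:
    if not parcellations:
        raise ValueError("no parcellations given")
    ref = parcellations[0].seed_set
    for p in parcellations[1:]:
        if p.seed_set.shape != ref.shape or not np.array_equal(
            p.seed_set.coordinates, ref.coordinates
        ):
            raise ValueError("parcellations must share the same seed set")
    return np.stack([p.labels for p in parcellations])


def coincidence_matrix(
    parcellations: list[Parcellation],
    threshold: float = DEFAULT_GROUP_THRESHOLD,
) -> np.ndarray:
    """Same-label co-occurrence fraction across subjects, thresholded.

    Entry (i, j) is the fraction of subjects in which seed voxels i and j
    carry the same label; entries below ``threshold`` are zeroed.  With a
    single subject the matrix is binary.
    """
    labels = _label_matrix(parcellations)
    same = (labels[:, :, None] == labels[:, None, :]).mean(axis=0)
    same[same < threshold] = 0.0
    return same


def group_scheme(
    similarity: np.ndarray,
    k: int,
    seed: int = 0,
    seed_set=None,
) -> np.ndarray | Parcellation:
    """Spectral clustering of the group similarity matrix.

    The diagonal is zeroed first (self-similarity carries no grouping
    information for normalized cut).  Returns canonical labels, or a
    :class:`Parcellation` when ``seed_set`` is given.
    """
    w = np.asarray(similarity, dtype=np.float64).copy()
    np.fill_diagonal(w, 0.0)
    labels = spectral_cluster(w, k, seed=seed)
    if seed_set is not None:
        return Parcellation(seed_set, labels, k)
    return labels


def overlap_counts(
    reference: np.ndarray, target: np.ndarray, k: int
) -> np.ndarray:
    """k x k matrix O[r, t] = #voxels with reference label r+1, target t+1."""
    reference = np.asarray(reference).ravel()
    target = np.asarray(target).ravel()
    o = np.zeros((k, k), dtype=np.int64)
    np.add.at(o, (reference - 1, target - 1), 1)
    return o


def match_labels(
    reference: Parcellation | np.ndarray, target: Parcellation | np.ndarray,
    k: int | None = None,
) -> np.ndarray:
    """Label bijection aligning ``target`` to ``reference``.

    Maximizes the total cluster-overlap count via the Hungarian algorithm;
    among equally optimal assignments, the lexicographically smallest
    mapping (as the tuple new-label-of-target-1, ..., new-label-of-
    target-k) is returned for determinism.

    Returns ``perm`` with ``perm[t - 1]`` = the reference label that
    target label t maps to.
    """
    ref = reference.labels if isinstance(reference, Parcellation) else np.asarray(reference)
    tgt = target.labels if isinstance(target, Parcellation) else np.asarray(target)
    if k is None:
        if isinstance(reference, Parcellation) and isinstance(target, Parcellation):
            if reference.k != target.k:
                raise ValueError(
                    f"cluster counts differ: {reference.k} vs {target.k}"
                )
            k = reference.k
        else:
            k = int(max(ref.max(), tgt.max()))
    o = overlap_counts(ref, tgt, k)
    best = o[linear_sum_assignment(-o)].sum()

    # build the lexicographically smallest optimal mapping greedily
    perm = np.zeros(k, dtype=np.int32)
    used: set[int] = set()
    fixed_value = 0
    for t in range(k):
        for r in range(k):
            if r in used:
                continue
            rest_r = [i for i in range(k) if i not in used and i != r]
            rest_t = list(range(t + 1, k))
            sub = o[np.ix_(rest_r, rest_t)] if rest_t else np.zeros((0, 0))
            rest_best = sub[linear_sum_assignment(-sub)].sum() if rest_t else 0
            if fixed_value + o[r, t] + rest_best == best:
                perm[t] = r + 1
                used.add(r)
                fixed_value += o[r, t]
                break
    return perm


def relabel_subjects(
    scheme: Parcellation, parcellations: list[Parcellation]
) -> tuple[list[Parcellation], list[np.ndarray]]:
    """Rename each subject's clusters to agree with the group scheme.

    Returns the relabeled parcellations and the permutation applied to
    each.  Idempotent: relabeling an already-aligned subject applies the
    identity.
    """
    relabeled, perms = [], []
    for p in parcellations:
        perm = match_labels(scheme, p)
        relabeled.append(p.relabeled(perm))
        perms.append(perm)
    return relabeled, perms


def mirror_x(data: np.ndarray) -> np.ndarray:
    """Flip the first voxel axis about the grid midplane (mid-sagittal
    mirror for a symmetric template grid)."""
    return np.flip(data, axis=0).copy()


def harmonize_hemispheres(
    left: Parcellation, right: Parcellation, mirror=mirror_x
) -> tuple[Parcellation, np.ndarray]:
    """Permute right-hemisphere labels to maximize overlap with the left
    after mirroring the right grid onto the left.

    If the mirrored supports do not overlap at all, a warning is issued
    and the identity permutation is applied.
    """
    if left.k != right.k:
        raise ValueError(f"cluster counts differ: {left.k} vs {right.k}")
    left_vol = left.to_volume().data
    right_vol = mirror(right.to_volume().data)
    both = (left_vol > 0) & (right_vol > 0)
    if not both.any():
        warnings.warn(
            "mirrored hemispheres do not overlap; keeping right labels",
            stacklevel=2,
        )
        return right, np.arange(1, right.k + 1, dtype=np.int32)
    perm = match_labels(left_vol[both], right_vol[both], k=left.k)
    return right.relabeled(perm), perm
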