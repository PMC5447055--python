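"""Multi-subject phantom cohorts with planted subregion structure.

The generator emulates the output of probabilistic tractography on a seed
region: every seed voxel belongs to one of ``k_true`` planted subregions,
each subregion has a prototype target pattern with disjoint support, and a
subject's profile at a seed voxel is a multinomial draw of ``n_samples``
streamlines (default 5,000) from

    (1 - noise_mix) * prototype[cluster] + noise_mix * uniform,

modulated by a mild 1/(1 + d/d0) distance decay that mimics the
distance-dependent drop-off of streamline counts.  Per-subject label
permutations reproduce the arbitrary cluster numbering of clustering
algorithms; optional boundary jitter perturbs each subject's planted
parcellation near cluster borders.

Everything is deterministic given ``master_seed``: per-subject RNG
substreams are derived from (master_seed, subject index), so cohorts are
bit-identical across runs and across worker counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as cio
from .connectivity import ConnectivityProfile
from .io import LabelVolume, SeedSet

__all__ = ["PhantomSpec", "PhantomCohort", "make_prototypes", "simulate_cohort",
           "simulate_bilateral_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for a phantom cohort.

    Defaults: a ~300-voxel seed block (6x6x8) in a 20^3 target grid at
    2.5 mm isotropic voxels, 4 planted subregions, 20 subjects, 5,000
    streamlines per seed voxel, 15% uniform noise mass, no jitter, with
    per-subject label permutation on.
    """

    roi_shape: tuple[int, int, int] = (6, 6, 8)
    k_true: int = 4
    n_subjects: int = 20
    target_shape: tuple[int, int, int] = (20, 20, 20)
    n_samples: int = 5000
    noise_mix: float = 0.15
    jitter: float = 0.0
    permute_labels: bool = True
    master_seed: int = 0
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    distance_bias: bool = True

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if any(r > t for r, t in zip(self.roi_shape, self.target_shape)):
            raise ValueError("roi_shape must fit inside target_shape")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a

    @property
    def roi_offset(self) -> tuple[int, int, int]:
        """ROI block placed at the center of the target grid."""
        return tuple(
            (t - r) // 2 for r, t in zip(self.roi_shape, self.target_shape)
        )


@dataclass
class PhantomCohort:
    """A simulated cohort: mask, seed order, planted truth, and counts.

    ``truth_labels[s]`` are subject s's planted labels *after* jitter and
    label permutation; ``canonical_labels`` is the group-level ground
    truth in canonical numbering.  ``permutations[s]`` maps canonical
    label c to subject s's stored label via ``permutations[s][c - 1]``.
    """

    spec: PhantomSpec
    mask: LabelVolume
    seed_set: SeedSet
    prototypes: np.ndarray  # (k_true, n_targets)
    canonical_labels: np.ndarray  # (n_seeds,)
    truth_labels: np.ndarray  # (n_subjects, n_seeds)
    permutations: np.ndarray  # (n_subjects, k_true)
    counts: list = field(default_factory=list)  # per subject (n_seeds, n_targets)

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects

    def profiles(self, subject: int) -> list[ConnectivityProfile]:
        """One :class:`ConnectivityProfile` per seed voxel, in seed order."""
        c = self.counts[subject]
        return [
            ConnectivityProfile(
                tuple(coord), c[i], tuple(self.spec.target_shape),
                self.spec.n_samples,
            )
            for i, coord in enumerate(self.seed_set.coordinates)
        ]

    def write(self, data_dir: str | Path, roi_name: str = "roi") -> None:
        """Persist the cohort in the pipeline's ingestion layout.

        ``<roi>_mask.nii`` plus per-subject ``sub-XXX/<roi>_profile.txt``
        count matrices (seed order x C-order target voxels) and plain-text
        truth sidecars.
        """
        data_dir = Path(data_dir)
        data_dir.mkdir(parents=True, exist_ok=True)
        cio.write_label_volume(self.mask, data_dir / f"{roi_name}_mask.nii")
        cio.write_matrix(
            self.canonical_labels[None, :].astype(float),
            data_dir / f"{roi_name}_truth_canonical.txt",
        )
        cio.write_matrix(
            self.truth_labels.astype(float),
            data_dir / f"{roi_name}_truth_subjects.txt",
        )
        for s in range(self.n_subjects):
            sub = data_dir / f"sub-{s:03d}"
            sub.mkdir(exist_ok=True)
            cio.write_matrix(
                self.counts[s].astype(float), sub / f"{roi_name}_profile.txt"
            )

    @staticmethod
    def subject_ids(n_subjects: int) -> list[str]:
        return [f"sub-{s:03d}" for s in range(n_subjects)]


def make_prototypes(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """``k_true`` probability vectors over the target grid.

    The grid is sliced into ``k_true`` slabs along its longest axis; each
    prototype gets random positive (gamma-distributed) weights on its own
    slab, normalized to sum 1.  Supports are disjoint, so pairwise cosine
    similarity is 0 (< 0.2 required).
    """
    if rng is None:
        rng = np.random.default_rng([spec.master_seed, 901])
    shape = tuple(spec.target_shape)
    axis = int(np.argmax(shape))
    if shape[axis] < spec.k_true:
        raise ValueError(
            f"target grid {shape} too small to place {spec.k_true} "
            "disjoint prototype patterns"
        )
    slabs = np.array_split(np.arange(shape[axis]), spec.k_true)
    n_targets = int(np.prod(shape))
    axis_index = np.indices(shape)[axis].ravel()
    protos = np.zeros((spec.k_true, n_targets))
    for c, slab in enumerate(slabs):
        support = np.isin(axis_index, slab)
        w = rng.gamma(2.0, 1.0, size=int(support.sum()))
        protos[c, support] = w / w.sum()
    sims = _pairwise_cosine(protos)
    if sims.max(initial=0.0) >= 0.2:
        raise ValueError("prototype patterns overlap too much (cosine >= 0.2)")
    return protos


def _pairwise_cosine(rows: np.ndarray) -> np.ndarray:
    unit = rows / np.linalg.norm(rows, axis=1, keepdims=True)
    g = unit @ unit.T
    return g[np.triu_indices(len(rows), k=1)]


def _canonical_labels(spec: PhantomSpec, seed_set: SeedSet) -> np.ndarray:
    """Slab partition of the ROI along its longest axis, labels 1..k_true."""
    axis = int(np.argmax(spec.roi_shape))
    offset = spec.roi_offset[axis]
    pos = seed_set.coordinates[:, axis] - offset
    bounds = np.cumsum(
        [len(s) for s in np.array_split(np.arange(spec.roi_shape[axis]), spec.k_true)]
    )
    return np.searchsorted(bounds, pos, side="right").astype(np.int32) + 1


def _jitter_labels(
    labels_vol: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Reassign voxels within ``radius`` (Chebyshev) of a cluster boundary
    to a neighboring cluster with probability 0.5."""
    size = 2 * int(np.ceil(radius)) + 1
    inside = labels_vol > 0
    lmax = ndimage.maximum_filter(labels_vol, size=size)
    big = np.iinfo(np.int32).max
    lmin = ndimage.minimum_filter(
        np.where(inside, labels_vol, big).astype(np.int64), size=size
    )
    # a different positive label exists within the Chebyshev window
    boundary = inside & ((lmax > labels_vol) | (lmin < labels_vol))
    out = labels_vol.copy()
    coords = np.argwhere(boundary)
    r = int(np.ceil(radius))
    for x, y, z in coords:
        if rng.random() >= 0.5:
            continue
        sl = tuple(
            slice(max(0, c - r), c + r + 1) for c in (x, y, z)
        )
        window = labels_vol[sl]
        own = labels_vol[x, y, z]
        others = np.unique(window[(window > 0) & (window != own)])
        if others.size:
            out[x, y, z] = rng.choice(others)
    return out


def _subject_counts(
    spec: PhantomSpec,
    prototypes: np.ndarray,
    cluster_of_seed: np.ndarray,
    bias: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    n_targets = prototypes.shape[1]
    probs = (1.0 - spec.noise_mix) * prototypes[cluster_of_seed - 1]
    probs = probs + spec.noise_mix / n_targets
    if bias is not None:
        probs = probs * bias
    probs = probs / probs.sum(axis=1, keepdims=True)
    return rng.multinomial(spec.n_samples, probs).astype(np.int32)


def _distance_bias(spec: PhantomSpec, seed_set: SeedSet) -> np.ndarray | None:
    if not spec.distance_bias:
        return None
    vs = np.asarray(spec.voxel_size_mm)
    targets = (
        np.indices(spec.target_shape).reshape(3, -1).T.astype(np.float64) * vs
    )
    seeds = seed_set.coordinates.astype(np.float64) * vs
    d = np.sqrt(((seeds[:, None, :] - targets[None, :, :]) ** 2).sum(-1))
    d0 = 0.5 * float((np.asarray(spec.target_shape) * vs).max())
    return 1.0 / (1.0 + d / d0)


def _build_mask(spec: PhantomSpec, mirror: bool = False) -> LabelVolume:
    data = np.zeros(spec.target_shape, dtype=np.int32)
    off = spec.roi_offset
    sl = tuple(slice(o, o + r) for o, r in zip(off, spec.roi_shape))
    data[sl] = 1
    if mirror:
        data = np.flip(data, axis=0).copy()
    return LabelVolume(data, spec.affine)


def simulate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a full cohort under ``spec`` (deterministic in master_seed)."""
    return _simulate(spec, mirror=False, stream_offset=2000)


def _simulate(spec: PhantomSpec, mirror: bool, stream_offset: int) -> PhantomCohort:
    mask = _build_mask(spec, mirror=mirror)
    seed_set = cio.extract_seed_coordinates(mask)
    prototypes = make_prototypes(spec)
    if mirror:
        k, n = prototypes.shape
        prototypes = (
            np.flip(prototypes.reshape((k,) + tuple(spec.target_shape)), axis=1)
            .reshape(k, n)
            .copy()
        )
        # canonical labels of the mirrored voxel
        base_mask = _build_mask(spec, mirror=False)
        base_seeds = cio.extract_seed_coordinates(base_mask)
        base_labels = _canonical_labels(spec, base_seeds)
        lut = {
            tuple(c): int(l)
            for c, l in zip(base_seeds.coordinates, base_labels)
        }
        x_max = spec.target_shape[0] - 1
        canonical = np.array(
            [
                lut[(x_max - x, y, z)]
                for x, y, z in seed_set.coordinates
            ],
            dtype=np.int32,
        )
    else:
        canonical = _canonical_labels(spec, seed_set)
    bias = _distance_bias(spec, seed_set)

    label_vol = np.zeros(spec.target_shape, dtype=np.int32)
    label_vol[tuple(seed_set.coordinates.T)] = canonical

    truth = np.empty((spec.n_subjects, len(seed_set)), dtype=np.int32)
    perms = np.empty((spec.n_subjects, spec.k_true), dtype=np.int32)
    counts: list[np.ndarray] = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng([spec.master_seed, stream_offset + s])
        if spec.jitter > 0:
            jittered_vol = _jitter_labels(label_vol, spec.jitter, rng)
            subj_canonical = jittered_vol[tuple(seed_set.coordinates.T)]
        else:
            subj_canonical = canonical
        counts.append(_subject_counts(spec, prototypes, subj_canonical, bias, rng))
        if spec.permute_labels:
            perm = rng.permutation(spec.k_true).astype(np.int32) + 1
        else:
            perm = np.arange(1, spec.k_true + 1, dtype=np.int32)
        perms[s] = perm
        truth[s] = perm[subj_canonical - 1]
    return PhantomCohort(
        spec=spec,
        mask=mask,
        seed_set=seed_set,
        prototypes=prototypes,
        canonical_labels=canonical,
        truth_labels=truth,
        permutations=perms,
        counts=counts,
    )


def simulate_bilateral_cohort(
    spec: PhantomSpec,
) -> tuple[PhantomCohort, PhantomCohort]:
    """A left cohort plus its mirror-image right cohort.

    The right hemisphere is the left flipped across the mid-sagittal
    (first-axis) midplane, with the same planted topology but independent
    multinomial noise.
    """
    left = _simulate(spec, mirror=False, stream_offset=2000)
    right = _simulate(spec, mirror=True, stream_offset=7000)
    return left, right
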