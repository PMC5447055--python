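"""From raw streamline-count profiles to the cross-correlation matrix.

Each seed voxel carries a whole-brain connectivity profile: the number of
sampled streamlines (default 5,000 per voxel) that visited each target
voxel.  Profiles are processed in a fixed order --

1. threshold: visitation probabilities p = count / n_samples at or below
   ``p_min`` (default 0.04%, i.e. 2 of 5,000 samples) are zeroed, removing
   the mostly-false-positive tail of probabilistic tractography;
2. distance correction: each retained entry is multiplied by the Euclidean
   distance (mm) between target- and seed-voxel centers, compensating the
   distance-dependent drop-off of streamline counts (the seed's own voxel,
   at distance zero, becomes 0);
3. downsampling: the target grid is partitioned into axis-aligned blocks
   (default 5 mm isotropic) and entries are summed within blocks, which
   conserves total corrected mass exactly.

The processed profiles are stacked (in seed order) into the native
connectivity matrix, and the Pearson correlation between its rows yields
the cross-correlation matrix that drives spectral clustering.

The threshold is applied to raw counts first because its cutoff is defined
in raw samples; correcting first would make "2 of 5,000" ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import SeedSet

__all__ = [
    "ConnectivityProfile",
    "threshold_profile",
    "distance_correct",
    "downsample_profile",
    "build_native_matrix",
    "cross_correlation",
    "DEFAULT_P_MIN",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_BLOCK_MM",
]

DEFAULT_P_MIN = 0.0004  # 0.04% == 2 of 5,000 samples
DEFAULT_N_SAMPLES = 5000
DEFAULT_BLOCK_MM = 5.0


@dataclass
class ConnectivityProfile:
    """Whole-brain streamline counts for one seed voxel.

    ``counts`` is stored flattened in C order over ``target_shape``; raw
    counts are integers but become real-valued after distance correction.
    """

    seed_coordinate: tuple[int, int, int]
    counts: np.ndarray  # (n_targets,) float64, C-order over target_shape
    target_shape: tuple[int, int, int]
    n_samples: int = DEFAULT_N_SAMPLES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64).ravel()
        if self.counts.size != int(np.prod(self.target_shape)):
            raise ValueError(
                f"counts length {self.counts.size} does not match target "
                f"grid {self.target_shape}"
            )
        if self.counts.min(initial=0.0) < 0:
            raise ValueError("streamline counts must be non-negative")


def threshold_profile(
    p: ConnectivityProfile,
    p_min: float = DEFAULT_P_MIN,
    n_samples: int | None = None,
) -> ConnectivityProfile:
    """Zero entries whose visitation probability is not above ``p_min``.

    An entry survives only if count / n_samples > p_min (strict): with the
    defaults, a count of 2 out of 5,000 (exactly 0.04%) is removed and 3
    is retained.  Idempotent.
    """
    if not 0 <= p_min < 1:
        raise ValueError(f"p_min must be in [0, 1), got {p_min}")
    n = p.n_samples if n_samples is None else n_samples
    counts = np.where(p.counts / n > p_min, p.counts, 0.0)
    return replace(p, counts=counts)


def distance_correct(
    p: ConnectivityProfile, voxel_size_mm: tuple[float, float, float]
) -> ConnectivityProfile:
    """Multiply each entry by its Euclidean distance (mm) from the seed.

    Proxies path-length correction: without the true streamline geometry
    the straight-line seed-to-target distance stands in for pathway length.
    The seed's own voxel (distance 0) is zeroed.
    """
    vs = np.asarray(voxel_size_mm, dtype=np.float64)
    grids = np.meshgrid(
        *(np.arange(s, dtype=np.float64) for s in p.target_shape), indexing="ij"
    )
    seed = np.asarray(p.seed_coordinate, dtype=np.float64)
    d2 = np.zeros(p.target_shape, dtype=np.float64)
    for axis in range(3):
        d2 += ((grids[axis] - seed[axis]) * vs[axis]) ** 2
    dist = np.sqrt(d2).ravel()
    return replace(p, counts=p.counts * dist)


def _block_factors(
    block_mm: float, voxel_size_mm: tuple[float, float, float]
) -> np.ndarray:
    vs = np.asarray(voxel_size_mm, dtype=np.float64)
    if block_mm <= 0:
        raise ValueError("block_mm must be positive")
    factors = block_mm / vs
    if (factors < 1 - 1e-9).any():
        raise ValueError(
            f"block ({block_mm} mm) smaller than native voxel {tuple(vs)} mm"
        )
    rounded = np.round(factors)
    if np.abs(factors - rounded).max() > 1e-9:
        raise ValueError(
            f"block ({block_mm} mm) must be an integer multiple of the "
            f"voxel size {tuple(vs)} mm"
        )
    return rounded.astype(np.int64)


def downsample_profile(
    p: ConnectivityProfile,
    block_mm: float = DEFAULT_BLOCK_MM,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Sum-pool the profile into ``block_mm`` axis-aligned blocks.

    Returns the flattened block vector.  Aggregation is by sum, so total
    mass is conserved exactly; trailing partial blocks are allowed.
    """
    f = _block_factors(block_mm, voxel_size_mm)
    data = p.counts.reshape(p.target_shape)
    for axis in range(3):
        n = data.shape[axis]
        edges = np.arange(0, n, f[axis])
        data = np.add.reduceat(data, edges, axis=axis)
    return data.ravel()


def build_native_matrix(
    profiles: list[ConnectivityProfile],
    p_min: float = DEFAULT_P_MIN,
    block_mm: float = DEFAULT_BLOCK_MM,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed_set: SeedSet | None = None,
) -> np.ndarray:
    """Process every profile (threshold, distance-correct, downsample) and
    stack the results row-wise in seed order.

    If ``seed_set`` is given, profiles must cover exactly its voxels in its
    order; a missing or misordered profile is an error.
    """
    if not profiles:
        raise ValueError("no profiles given")
    shapes = {p.target_shape for p in profiles}
    if len(shapes) != 1:
        raise ValueError(f"profiles on different target grids: {shapes}")
    if seed_set is not None:
        got = [tuple(p.seed_coordinate) for p in profiles]
        want = [tuple(c) for c in seed_set.coordinates]
        if got != want:
            raise ValueError("profiles do not cover the seed set in order")
    rows = []
    for p in profiles:
        q = threshold_profile(p, p_min=p_min)
        q = distance_correct(q, voxel_size_mm)
        rows.append(downsample_profile(q, block_mm, voxel_size_mm))
    return np.vstack(rows)


def cross_correlation(native: np.ndarray) -> np.ndarray:
    """Pearson correlation between every pair of native-matrix rows.

    Rows with zero variance correlate 0 with everything and 1 with
    themselves, keeping the matrix usable without undefined divisions.
    The result is symmetric with unit diagonal and entries in [-1, 1].
    """
    native = np.asarray(native, dtype=np.float64)
    if native.ndim != 2 or native.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    centered = native - native.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= 1e-300
    safe = np.where(degenerate, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return corr
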