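import numpy as np
import pytest

from cbparc.io import SeedSet
from cbparc.parcellate import Parcellation
from cbparc.synthetic import PhantomSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_spec():
    """A fast 64-seed-voxel phantom: 3 planted clusters, 6 subjects."""
    return PhantomSpec(
        roi_shape=(4, 4, 4),
        k_true=3,
        n_subjects=6,
        target_shape=(10, 10, 10),
        noise_mix=0.1,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


def grid_parcellation(labels_3d: np.ndarray) -> Parcellation:
    """Wrap a dense 3D label array (no background) as a Parcellation."""
    labels_3d = np.asarray(labels_3d)
    coords = np.argwhere(np.ones_like(labels_3d, dtype=bool))
    seeds = SeedSet(coords, labels_3d.shape)
    labels = labels_3d[tuple(coords.T)]
    return Parcellation(seeds, labels, int(labels.max()))


@pytest.fixture
def make_grid_parcellation():
    return grid_parcellation
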