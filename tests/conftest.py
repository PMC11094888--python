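import numpy as np
import pytest

from dynrad.config import SimulationConfig, PreprocessParams
from dynrad.synthetic import PhaseStack


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Small, fast cohort configuration used across tests."""
    return SimulationConfig(
        n_patients=12,
        grid_shape=(16, 20, 20),
        voxel_spacing=(1.5, 1.5, 1.5),
        lesion_radius_range=(4.0, 6.0),
        n_genes=300,
        n_planted_degs=20,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def label_only_config():
    """Minimal-geometry config for label/covariate statistics at large n."""
    return SimulationConfig(
        n_patients=2000,
        grid_shape=(8, 10, 10),
        voxel_spacing=(1.5, 1.5, 1.5),
        lesion_radius_range=(2.0, 3.0),
        n_genes=50,
        n_planted_degs=5,
        rng_seed=11,
    )


def make_sphere_mask(shape, radius_vox, center=None):
    grids = np.indices(shape).astype(float)
    if center is None:
        center = [(s - 1) / 2 for s in shape]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius_vox ** 2


@pytest.fixture
def sphere_stack():
    """Two-phase stack with a ~1000-voxel sphere at 1 mm spacing."""
    r = (1000 * 3 / (4 * np.pi)) ** (1 / 3)
    mask = make_sphere_mask((26, 26, 26), r)
    rng = np.random.default_rng(0)
    img = np.stack([rng.normal(100, 5, mask.shape) + np.where(mask, v, 0)
                    for v in (0.0, 40.0)])
    return PhaseStack(image=img, mask=mask, spacing=(1, 1, 1),
                      phase_order=(0, 1))


@pytest.fixture(scope="session")
def preprocess_params():
    return PreprocessParams()
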