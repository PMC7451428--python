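import numpy as np
import pytest

from seedgc import CohortConfig, TaskDesign, Volume4D, generate_cohort, generate_task_design
from seedgc.design import Block


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data: np.ndarray, tr: float = 2.5, voxel_size: float = 3.0,
                mask: np.ndarray | None = None) -> Volume4D:
    """Volume with a centred isotropic affine, for constructed fixtures."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
    affine[:3, 3] = -(np.asarray(data.shape[:3]) - 1) / 2.0 * voxel_size
    return Volume4D(data=data, affine=affine, tr=tr, mask=mask)


@pytest.fixture
def noise_volume(rng):
    return make_volume(rng.standard_normal((8, 8, 8, 40)))


@pytest.fixture(scope="session")
def default_design():
    return generate_task_design(7, 2, rng_seed=0)


def tiny_cohort_config(**overrides) -> CohortConfig:
    """2+2 subjects on a small grid with a short scan: fast I/O round-trips."""
    cfg = CohortConfig(
        n_sz=overrides.pop("n_sz", 2),
        n_hc=overrides.pop("n_hc", 2),
        grid_shape=(10, 10, 10),
        node_positions={"seed": (6.0, 6.0, 0.0), "target": (-6.0, -6.0, 0.0)},
        n_rest_vols=40,
        n_discard=2,
        n_blocks_per_session=2,
        n_sessions=1,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def demo_cohort():
    """One desk-scale cohort shared by the slower integration tests."""
    return generate_cohort(CohortConfig.demo(), rng_seed=7)
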