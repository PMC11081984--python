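import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lcqspatial as L

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def minimal_ring_config():
    """One lobule with a single 12-cell alveolus and nothing else."""
    return L.SimConfig(
        seed=7,
        field_width=600.0,
        field_height=600.0,
        n_lobules=1,
        alveoli_per_lobule_mean=1,
        lobule_radius=120.0,
        cells_per_alveolus_mean=12,
        shed_cell_rate=0.0,
        stromal_density=0.0,
    )


@pytest.fixture(scope="session")
def small_gland():
    """A compact 4-lobule gland reused by I/O and pipeline tests."""
    cfg = L.SimConfig(seed=11, field_width=1500.0, field_height=1500.0, n_lobules=4)
    pattern, alveoli, adjacency, mask = L.simulate_tissue(cfg)
    return cfg, pattern, alveoli, adjacency, mask


@pytest.fixture(scope="session")
def default_gland():
    """One gland under the full default study conditions."""
    cfg = L.SimConfig(seed=1)
    pattern, alveoli, adjacency, mask = L.simulate_tissue(cfg)
    return cfg, pattern, alveoli, adjacency, mask


def random_pattern(seed, n=200, width=1000.0, p_pos=0.3):
    """Uniform random marked pattern used across LCQ tests."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, width, (n, 2))
    lab = rng.random(n) < p_pos
    cells = [
        L.CellRecord(i, float(x), float(y), bool(l), "stromal")
        for i, ((x, y), l) in enumerate(zip(xy, lab))
    ]
    return L.PointPattern(cells=cells, domain=(width, width))
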