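import numpy as np
import pytest

import urbanflow as uf
from urbanflow.environment import LandUse, LandUseQuota, SizeDistribution

#: Table-1 percentages scaled to a 20x20 grid, with proportionally small
#: cluster caps — a fast stand-in city for unit tests.
SMALL_QUOTAS = (
    LandUseQuota(LandUse.RESIDENTIAL, 136, 40),
    LandUseQuota(LandUse.EMPLOYMENT, 40, 20),
    LandUseQuota(LandUse.PUBLIC_BUILDING, 48, 12),
    LandUseQuota(LandUse.MIXED_R_E_RETAIL, 96, 15),
    LandUseQuota(LandUse.ENTERTAINMENT_RETAIL, 32, 8),
    LandUseQuota(LandUse.PUBLIC_OPEN_SPACE, 48, 10),
)


@pytest.fixture(scope="session")
def small_env():
    return uf.generate_environment(quotas=SMALL_QUOTAS, dims=(20, 20), rng=7)


@pytest.fixture(scope="session")
def default_env():
    return uf.generate_environment(rng=123)


@pytest.fixture(scope="session")
def default_table():
    return uf.ProbabilityTable.default()


@pytest.fixture(scope="session")
def scaled_run():
    """A 500-agent, 7-day run with shipped defaults, shared across tests."""
    cfg = uf.default_config()
    cfg.agents.n = 500
    cfg.run.days = 7
    seed = np.random.SeedSequence(11)
    env_seq, _ = seed.spawn(2)
    env = cfg.build_environment(np.random.default_rng(env_seq))
    log = uf.run_simulation(cfg, env=env, seed=np.random.SeedSequence(11))
    return env, log


def make_uniform_grid(rows, cols, land_use=LandUse.RESIDENTIAL, cell_size_m=25.0):
    """Hand-built single-land-use grid for degenerate-geometry tests."""
    lu = np.full((rows, cols), int(land_use), dtype=np.int8)
    cid = np.zeros((rows, cols), dtype=np.int32)
    theta = np.ones((rows, cols))
    return uf.EnvironmentGrid(lu, cid, theta, cell_size_m)
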