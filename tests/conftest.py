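import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import effortmap as em

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_world() -> em.World:
    """Three countries over a short span — cheap, reused across tests."""
    cfg = em.WorldConfig(n_countries=3, year_start=1950, year_end=1980, rng_seed=11)
    return em.generate_world(cfg)


@pytest.fixture(scope="session")
def small_result(small_world) -> em.PipelineResult:
    return em.run_pipeline(small_world)


@pytest.fixture(scope="session")
def toy_grid_pair():
    """Two random positive 10x10 effort tables on the cell-centre lattice."""
    rng = np.random.default_rng(3)
    lat = np.repeat(np.arange(10) * 0.5 + 0.25, 10)
    lon = np.tile(np.arange(10) * 0.5 + 0.25, 10)
    a = pd.DataFrame({"lat": lat, "lon": lon, "effort": rng.lognormal(0, 1, 100)})
    b = pd.DataFrame({"lat": lat, "lon": lon, "effort": rng.lognormal(0, 1, 100)})
    return a, b
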