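import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nichemap import simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_fov():
    """One reproducible small FOV with leukemia cells and transcripts."""
    params = simulate.TissueParams(
        fov_width=130.0, fov_height=90.0, n_cells=70, n_genes=24,
        leukemia_fraction=0.1, seed=11,
    )
    cells, transcripts, cm, truth = simulate.simulate_fov(params)
    return params, cells, transcripts, cm, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
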