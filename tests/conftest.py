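import numpy as np
import pytest

from elopt import ADMMConfig, CaseConfig, default_objectives, generate_case


@pytest.fixture(scope="session")
def small_case():
    """Two-beam ellipsoid phantom, ~10 layers / ~490 spots on a 20^3 grid."""
    return generate_case(CaseConfig(seed=1))


@pytest.fixture(scope="session")
def small_terms(small_case):
    return default_objectives(small_case)


@pytest.fixture(scope="session")
def tiny_case():
    """Single-beam slab phantom, small enough for full pipelines in ~1 s."""
    return generate_case(
        CaseConfig(grid_shape=(14, 14, 14), seed=7, beam_angles_deg=(0.0,),
                   ctv_radii_mm=(9.0, 8.0, 8.0))
    )


@pytest.fixture(scope="session")
def tiny_terms(tiny_case):
    return default_objectives(tiny_case)


@pytest.fixture()
def fast_config():
    """Optimizer settings sized so a full solve takes ~1 s."""
    return ADMMConfig(icr_outer_iter=6, admm_max_iter=4, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
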