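import numpy as np
import pytest

from burstabc.promoter_sim import (
    KineticParams,
    PromoterModelSpec,
    build_topology,
    simulate_population,
)
from burstabc.synthetic_data import add_measurement_noise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_params():
    """Two-state kinetics of the reference fit (ON 0.6 min, OFF 50 min, b 10)."""
    return KineticParams(
        t_on=0.6, t_off=50.0, burst_size=10.0,
        cv_ext={"k_init": 0.35, "k_elong": 0.35},
    )


@pytest.fixture(scope="session")
def small_dataset(reference_params):
    """A 20-cell observed steady-state dataset reused across feature tests."""
    model = PromoterModelSpec(build_topology("1-1-5"), reference_params)
    rng = np.random.default_rng(777)
    ds = simulate_population(model, 20, rng=rng)
    return add_measurement_noise(ds, rng=rng)
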