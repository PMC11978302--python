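import numpy as np
import pytest

from fibrodyn import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_proteins=200,
        frac_fibrosis_tracking=0.1, frac_declining=0.1,
        frac_solubility_shift=0.1,
        afm_grid=(4, 9), afm_maps_per_treatment=2,
        seed=42,
    )
    return simulate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
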