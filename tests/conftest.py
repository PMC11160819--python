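import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from pgskit.simulate import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def small_sim():
    """Three moderately differentiated populations, shared across tests."""
    return simulate_panel(
        SimulationConfig(
            n_pops=3,
            fst=0.1,
            n_ref_per_pop=40,
            n_target_per_pop=25,
            m_variants=600,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def two_pop_sim():
    """Two well-separated populations for PCA-behaviour tests."""
    return simulate_panel(
        SimulationConfig(
            n_pops=2,
            fst=0.1,
            n_ref_per_pop=60,
            n_target_per_pop=20,
            m_variants=800,
            seed=23,
        )
    )
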