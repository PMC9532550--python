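import numpy as np
import pytest

from dtims import (
    REFERENCE_CONFIG,
    REFERENCE_SPECIES,
    InjectionProgram,
    run_counterbalance,
    simulate_spectrum,
)

#: Slab width of the reference gate, m.
L_ION_REF = 1e-4


@pytest.fixture(scope="session")
def ref_species():
    return REFERENCE_SPECIES


@pytest.fixture(scope="session")
def ref_config():
    return REFERENCE_CONFIG


@pytest.fixture(scope="session")
def ref_pulsed():
    """Simulated pulsed arrival-time spectrum of the reference scenario."""
    return simulate_spectrum(
        REFERENCE_CONFIG, REFERENCE_SPECIES,
        InjectionProgram(mode="pulsed", L_ion=L_ION_REF))


@pytest.fixture(scope="session")
def ref_inverse():
    return simulate_spectrum(
        REFERENCE_CONFIG, REFERENCE_SPECIES,
        InjectionProgram(mode="inverse", L_ion=L_ION_REF))


@pytest.fixture(scope="session")
def ref_result():
    """Full counterbalance run of the reference scenario, shared across tests."""
    return run_counterbalance(REFERENCE_CONFIG, REFERENCE_SPECIES, L_ION_REF)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
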