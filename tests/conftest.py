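import warnings

import pytest

from voctrait.simulate import SimulationScenario, simulate


@pytest.fixture(scope="session")
def default_study():
    """One default-conditions synthetic study shared by read-only tests."""
    return simulate(SimulationScenario(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast pipeline-level tests."""
    sc = SimulationScenario(n_species=12, n_ptr_compounds=30, n_gc_compounds=12,
                            seed=5)
    return sc, simulate(sc)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
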