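import numpy as np
import pytest

from gipk import (
    AbsorptionParams,
    PhysiologyParams,
    load_drug_fixture,
    table4_fixture,
)


@pytest.fixture(scope="session")
def phys() -> PhysiologyParams:
    return PhysiologyParams()


@pytest.fixture(scope="session")
def aprepitant():
    return load_drug_fixture("Aprepitant").with_dose(80.0)


@pytest.fixture(scope="session")
def aprepitant_params() -> AbsorptionParams:
    return table4_fixture("Aprepitant")


@pytest.fixture(scope="session")
def aprepitant_curve(aprepitant, phys, aprepitant_params):
    """One 12 h forward simulation shared by several read-only tests."""
    from gipk import simulate_full

    return simulate_full(
        aprepitant, phys, aprepitant_params, t_end=43200.0, audit=True
    )
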