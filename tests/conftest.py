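import pytest

from oxidha import reference_method
from oxidha.simulate import SamplePlan


@pytest.fixture(scope="session")
def hdohe_method():
    return reference_method("HDoHE")


@pytest.fixture(scope="session")
def hpdohe_method():
    return reference_method("HpDoHE")


@pytest.fixture
def noise_free_plan():
    """Deterministic plan: no baseline noise, no area noise."""
    return SamplePlan(
        analyte_concentrations={},
        noise_sigma=0.0,
        area_cv=0.0,
        seed=0,
    )
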