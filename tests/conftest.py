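import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from peds_or_cea.burden import DiscountSpec, TreatmentParams, default_catalog
from peds_or_cea.model import CEAModel
from peds_or_cea.registry import RegistryParams, generate_registry


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def disc():
    return DiscountSpec(0.03)


@pytest.fixture(scope="session")
def annual_registry():
    """A 343-case synthetic annual demand registry."""
    return generate_registry(RegistryParams(n_cases=343, months_span=12.0, seed=42))


@pytest.fixture(scope="session")
def small_registry():
    """A 12-case registry for brute-force oracle comparisons."""
    return generate_registry(RegistryParams(n_cases=12, months_span=12.0, seed=5))


@pytest.fixture(scope="session")
def default_model():
    """The shipped study conditions: calibrated model at seed 0."""
    return CEAModel.default(seed=0)
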