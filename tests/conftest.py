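import pytest
from hypothesis import settings

from nutrikin import Environment, OrganismConfig, QuotaParams, TransporterParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def env() -> Environment:
    """Default seawater environment (paper-standard constants)."""
    return Environment()


@pytest.fixture(scope="session")
def default_quota() -> QuotaParams:
    return QuotaParams()


@pytest.fixture(scope="session")
def default_transporter() -> TransporterParams:
    return TransporterParams()


@pytest.fixture(scope="session")
def c150_10um() -> OrganismConfig:
    """The reference operating configuration: fixed-density cell, 10 μm,
    non-motile, standard quota and transporter parameters."""
    return OrganismConfig(ESD=10.0, carbon_model="C150", motion="none")
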