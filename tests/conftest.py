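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


@pytest.fixture(scope="session")
def default_config():
    from cellcycler import CellModelConfig

    return CellModelConfig(n_compartments=50, doubling_time=24.0,
                           phase_fractions=(0.2, 0.3, 0.4, 0.1))


@pytest.fixture(scope="session")
def case1():
    from cellcycler import load_fixture

    return load_fixture("case1")
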