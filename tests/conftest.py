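import pytest
from hypothesis import HealthCheck, settings

from urnmap.fixtures import generate_toy_complex, prototype_fixture_spec
from urnmap.urn import PrototypeReference

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dr_toy():
    """Toy DR prototype groove: CLIP 18-mer with the unified DR SC triples planted."""
    return generate_toy_complex(prototype_fixture_spec("dr"))


@pytest.fixture(scope="session")
def dq_toy():
    return generate_toy_complex(prototype_fixture_spec("dq"))


@pytest.fixture(scope="session")
def dr_proto(dr_toy):
    return PrototypeReference.from_complex(dr_toy.complex, "dr")


@pytest.fixture(scope="session")
def dq_proto(dq_toy):
    return PrototypeReference.from_complex(dq_toy.complex, "dq")
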