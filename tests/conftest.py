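import pytest
from hypothesis import HealthCheck, settings

from helmetcoder import load_default_library

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return load_default_library()
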