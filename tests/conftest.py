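import pytest

from ribarriers.datasets import salvia_field_study


@pytest.fixture(scope="session")
def study():
    return salvia_field_study()
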