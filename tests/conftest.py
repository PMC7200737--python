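import pytest

from gpcrdyn import FieldConditions, SpinParams


@pytest.fixture
def params_38ns() -> SpinParams:
    """Default amide spin parameters at the measured tumbling time."""
    return SpinParams(tau_c=38.0)


@pytest.fixture
def field_14t() -> FieldConditions:
    return FieldConditions(b0=14.1)


@pytest.fixture
def field_21t() -> FieldConditions:
    return FieldConditions(b0=21.2)
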