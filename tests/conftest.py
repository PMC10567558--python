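import pytest

from hairpincode import (ConversionModel, DecodingModel, ResolverParams,
                         make_controls)
from hairpincode.simulate import CONTROL_POOL_WEIGHTS


@pytest.fixture(scope="session")
def five_letter():
    return DecodingModel.five_letter()


@pytest.fixture(scope="session")
def six_letter():
    return DecodingModel.six_letter()


@pytest.fixture(scope="session")
def controls():
    """The three spike-in ground-truth controls (references + methylome)."""
    return make_controls(seed=7)


@pytest.fixture(scope="session")
def control_weights():
    return dict(CONTROL_POOL_WEIGHTS)


@pytest.fixture()
def resolver_params():
    from hairpincode import DEFAULT_HAIRPIN
    return ResolverParams(hairpin=DEFAULT_HAIRPIN)


def perfect_chemistry():
    return ConversionModel()
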