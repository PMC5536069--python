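import pytest

from batfusion import (
    load_propensity_table,
    syb2_cterminal_segment,
    syx1a_cterminal_segment,
)


@pytest.fixture(scope="session")
def table():
    return load_propensity_table("chou-fasman")


@pytest.fixture(scope="session")
def syb2():
    return syb2_cterminal_segment()


@pytest.fixture(scope="session")
def syx1a():
    return syx1a_cterminal_segment()
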