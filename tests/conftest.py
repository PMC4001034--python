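import pytest

from connset import explicit

from helpers import FIG2A_PAIRS


@pytest.fixture
def m_fig2():
    """The worked-example 5x5 mask with six connections."""
    return explicit(FIG2A_PAIRS)
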