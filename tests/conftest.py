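import pytest

from columnhough import (
    fixture_fig3,
    fixture_fig5,
    make_bar_set,
    build_network,
    set_binary_config,
    analytic_config,
)


@pytest.fixture(scope="session")
def fig3():
    return fixture_fig3()


@pytest.fixture(scope="session")
def fig5():
    return fixture_fig5()


@pytest.fixture(scope="session")
def analytic_net9(fig3):
    """The 9x9 net under its analytic (Hough-derived) binary configuration."""
    config = analytic_config(9, 9, fig3)
    return set_binary_config(build_network(9, 9), config.bits)
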