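import numpy as np
import pytest

from chloroflux.network import builtin_network, parse_network


@pytest.fixture(scope="session")
def cbc_toy():
    return builtin_network("cbc_toy")


@pytest.fixture(scope="session")
def minimal_chain():
    return builtin_network("minimal_chain")


@pytest.fixture(scope="session")
def one_pool():
    """Single 1-carbon pool fed by CO2 at 50% enrichment, turnover 0.1 s-1.

    Closed form: E(t) = 0.5 * (1 - exp(-0.1 t)).
    """
    return parse_network(
        "up: CO2 -> A | a : a\nout: A -> ASINK | a : a",
        pools={"A": 1.0}, fluxes={"up": 0.1, "out": 0.1},
        inputs={"CO2": 0.5})


@pytest.fixture(scope="session")
def two_pool():
    """Two 1-carbon pools in series; double-exponential enrichment."""
    return parse_network(
        "up: CO2 -> A | a : a\nab: A -> B | a : a\nout: B -> BSINK | a : a",
        pools={"A": 1.0, "B": 2.0},
        fluxes={"up": 0.1, "ab": 0.1, "out": 0.1},
        inputs={"CO2": 0.5})


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
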