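import numpy as np
import pytest

from isletburst import ParameterSet, Variant


@pytest.fixture(scope="session")
def wt():
    return ParameterSet.default(Variant.WT_KATP)


@pytest.fixture(scope="session")
def ko_kir():
    return ParameterSet.default(Variant.KO_KIR21)


@pytest.fixture(scope="session")
def ko_leak():
    return ParameterSet.default(Variant.KO_LEAK_KCA)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170727)


@pytest.fixture(scope="session")
def ko_trace():
    """One medium-length Kir2.1-knockout simulation shared across tests."""
    from isletburst import integrate
    p = ParameterSet.default(Variant.KO_KIR21)
    return integrate(p, 60.0)
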