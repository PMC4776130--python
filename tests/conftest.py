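import numpy as np
import pytest

from phtmd import fixtures


@pytest.fixture(scope="session")
def asp_system():
    return fixtures.model_compound("asp")


@pytest.fixture(scope="session")
def acfca_system():
    return fixtures.acfca_like()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_acid_system(w12=1.0):
    """Two coupled acids (pKa 4.0 / 5.0) used by several hand-arithmetic oracles."""
    from phtmd.titration_model import SiteSystem, TitratableSite

    return SiteSystem(
        [
            TitratableSite("a", 4.0, 0, -1, "acid"),
            TitratableSite("b", 5.0, 0, -1, "acid"),
        ],
        np.array([[0.0, w12], [w12, 0.0]]),
    )
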