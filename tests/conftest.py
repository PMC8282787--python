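import numpy as np
import pytest

from columnmorph import generate_columns, reference_scenario
from columnmorph.synthetic import SyntheticConfig, generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_paper_ds():
    """paper_like scenario at 12 species: shared across read-only tests."""
    return generate_columns(reference_scenario("paper_like", n_species=12, seed=3))


@pytest.fixture(scope="session")
def tree32():
    """A fixed 32-tip ultrametric pure-birth tree (root age 60 Ma)."""
    return generate_tree(SyntheticConfig(n_species=32, seed=11))


def random_rotation(rng):
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
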