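import numpy as np
import pytest

from rnaprecis.synthetic import (SyntheticConfig, build_cartesian,
                                 sample_gold_standard)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


#: Canonical A-form-like dihedral set (delta-, eps, zeta, alpha, beta,
#: gamma, delta) used by many geometry tests.
A_FORM = np.array([84.0, 212.0, 288.0, 295.0, 172.0, 54.0, 84.0])


@pytest.fixture
def a_form_suite():
    return build_cartesian(A_FORM, "P33")


@pytest.fixture(scope="session")
def gold_standard():
    """One shared synthetic gold standard at the default study
    conditions (sigma = 8 deg); session-scoped because generation and
    training reuse it."""
    return sample_gold_standard(SyntheticConfig(seed=42))


def random_rigid(rng):
    """Random rotation matrix + translation for invariance tests."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-15, 15, size=3)
    return R, t
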