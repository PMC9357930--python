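import numpy as np
import pytest

from limbkin import AnthroProfile, build_chain


@pytest.fixture(scope="session")
def profile():
    # tall male athlete (1.90 m, 78 kg)
    return AnthroProfile("male", 1.90, 78.0)


@pytest.fixture(scope="session")
def chain(profile):
    return build_chain(profile)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_valid_q(chain, rng, scale=0.4):
    """Random coordinates respecting the elbow flexion bounds."""
    q = rng.uniform(-scale, scale, chain.n_q)
    for side in ("L", "R"):
        k = chain.q_index[(f"elbow_{side}", "flex_ext")]
        q[k] = rng.uniform(0.1, 2.0)
    return q
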