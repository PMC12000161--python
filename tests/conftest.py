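import numpy as np
import pytest

from chelamorph import SpeciesTemplate


def random_spd(rng: np.random.Generator, dim: int, cond: float = 50.0) -> np.ndarray:
    """Random SPD matrix with controlled condition number."""
    q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    lam = np.exp(rng.uniform(0.0, np.log(cond), size=dim))
    return (q * lam) @ q.T


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_template():
    """A genuinely featureless template: no tip wedge, no ascending ramus."""
    return SpeciesTemplate(label="flat", plateau_depth=0.0, basal_height=0.0)


@pytest.fixture
def default_template():
    return SpeciesTemplate(label="base")
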