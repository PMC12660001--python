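import numpy as np
import pytest

from ea_align import RatingCurve, Srvf, uniform_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def smooth_curve():
    """A smooth, nonmonotone test curve on a dense grid."""
    t = uniform_grid(2001)
    return RatingCurve(t, 5.0 + 2.0 * np.sin(3 * np.pi * t) + t**2)


def random_srvf_pair(n: int, rng: np.random.Generator) -> tuple[Srvf, Srvf]:
    g = uniform_grid(n)
    return Srvf(g, rng.normal(size=n)), Srvf(g, rng.normal(size=n))
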