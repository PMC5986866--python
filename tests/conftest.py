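import numpy as np
import pytest

from walshscape import Landscape


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def random_landscape(rng):
    def make(L: int, with_var: bool = False) -> Landscape:
        W = rng.normal(size=2**L)
        var = rng.random(2**L) * 0.01 if with_var else None
        return Landscape(L=L, W=W, var=var)

    return make
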