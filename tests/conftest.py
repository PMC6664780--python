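import numpy as np
import pytest

from loopforge import fixtures as fx
from loopforge.motifs import build_pwm


@pytest.fixture(scope="session")
def loop_cohort():
    return fx.make_loop_cohort(seed=11, n_loops=60)


@pytest.fixture(scope="session")
def pwm():
    return build_pwm(fx.ctcf_like_pfm())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
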