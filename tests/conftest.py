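import numpy as np
import pytest

from mklpet import phantom as ph


@pytest.fixture(scope="session")
def default_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def default_atlas(default_spec):
    return ph.make_toy_atlas(default_spec)


@pytest.fixture(scope="session")
def small_spec():
    return ph.PhantomSpec.small(noise_sd=0.2)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return ph.make_toy_atlas(small_spec)


@pytest.fixture(scope="session")
def strong_spec():
    return ph.PhantomSpec.strong()


@pytest.fixture(scope="session")
def strong_atlas(strong_spec):
    return ph.make_toy_atlas(strong_spec)


@pytest.fixture(scope="session")
def strong_cohort_small(strong_spec, strong_atlas):
    """18 subjects (8 PD / 5 MSA / 5 PSP) with pronounced effects."""
    return ph.simulate_cohort(
        strong_spec, {"PD": 8, "MSA": 5, "PSP": 5}, seed=11, atlas=strong_atlas
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
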