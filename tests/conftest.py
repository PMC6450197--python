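import numpy as np
import pytest

from mers import EngineConfig, StudyConfig, generate_bank
from mers.item_bank import Item


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bank1():
    return generate_bank("bank1", n_items=200, n_dims=3, seed=7)


@pytest.fixture
def bank2():
    return generate_bank("bank2", n_items=200, n_dims=3, seed=7)


@pytest.fixture
def multi_config():
    return EngineConfig(mode="multi", outcome="accuracy", n_dims=3)


def make_item(beta=0.0, loadings=(1, 1, 0), slopes=None):
    if slopes is None:
        slopes = tuple(float(l) for l in loadings)
    return Item(item_id=1, difficulty=beta, loadings=loadings, gen_slopes=slopes)


# ---- expensive paper-default runs shared by the acceptance tests ----

@pytest.fixture(scope="session")
def paper_config():
    return StudyConfig(seed=1)


@pytest.fixture(scope="session")
def study1_results(paper_config):
    from mers import run_study1

    return run_study1(paper_config)


@pytest.fixture(scope="session")
def study2_results(paper_config):
    from mers import run_study2

    return run_study2(paper_config)


@pytest.fixture(scope="session")
def study3_results(paper_config):
    from mers import run_study3

    return run_study3(paper_config)
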