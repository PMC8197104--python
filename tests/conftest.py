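import numpy as np
import pandas as pd
import pytest

from comfortrisk.linkage import link
from comfortrisk.simulate import GeneratorConfig, generate_accidents, generate_climate


@pytest.fixture(scope="session")
def small_cfg():
    """One city, two districts, one simulated year, scaled-down rates."""
    return GeneratorConfig(
        years=1,
        seed=20070101,
        layout={"Seoul": ("Gangbuk-gu", "Jung-gu")},
        rate_scale=0.05,
    )


@pytest.fixture(scope="session")
def small_climate(small_cfg):
    return generate_climate(small_cfg)


@pytest.fixture(scope="session")
def small_accidents(small_cfg, small_climate):
    return generate_accidents(small_climate, small_cfg)


@pytest.fixture(scope="session")
def small_linked(small_accidents, small_climate):
    linked, report = link(small_accidents, small_climate, policy="strict")
    assert report.n_unmatched == 0
    return linked


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
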