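import numpy as np
import pytest

import wexdce as w


@pytest.fixture(scope="session")
def human_protocol():
    return w.human_dce_protocol()


@pytest.fixture(scope="session")
def phantom():
    """Small noisy tumor phantom shared by geometry/prediction tests."""
    return w.generate_dce_phantom(
        grid=(48, 48), protocol=w.human_dce_protocol(n_frames=90), seed=7
    )


@pytest.fixture(scope="session")
def biopsy_table():
    return w.generate_biopsy_table(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_two_site(rng) -> w.TwoSiteParams:
    """Random but physiologic 2SX parameter draw."""
    return w.TwoSiteParams(
        p_i=rng.uniform(0.3, 0.9),
        k_io=rng.uniform(0.0, 20.0),
        R1_i=rng.uniform(0.2, 2.0),
        R1_o=rng.uniform(0.2, 30.0),
    )


def random_three_site(rng) -> w.ThreeSiteParams:
    p_b = rng.uniform(0.01, 0.15)
    p_o = rng.uniform(0.1, 0.5)
    return w.ThreeSiteParams(
        p_b=p_b,
        p_o=p_o,
        p_i=1.0 - p_b - p_o,
        k_bo=rng.uniform(0.0, 10.0),
        k_io=rng.uniform(0.0, 15.0),
        R1_b0=rng.uniform(0.3, 3.0),
        R1_o0=rng.uniform(0.3, 3.0),
        R1_i=rng.uniform(0.3, 2.0),
    )
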