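import numpy as np
import pytest

from medphylo.genome_model import CopyNumberProfile, GenomeLayout
from medphylo.med_model import build_event_model


@pytest.fixture(scope="session")
def model8():
    """Default event model: cap 8, WGD as +1 on non-zero segments."""
    return build_event_model(cap=8)


@pytest.fixture(scope="session")
def model8_nowgd():
    return build_event_model(cap=8, wgd_enabled=False)


@pytest.fixture(scope="session")
def model8_double():
    return build_event_model(cap=8, wgd_mode="double")


@pytest.fixture(scope="session")
def model3():
    """Small-alphabet model for oracle comparisons: cap 3."""
    return build_event_model(cap=3)


@pytest.fixture(scope="session")
def model3_nowgd():
    return build_event_model(cap=3, wgd_enabled=False)


@pytest.fixture
def layout22():
    return GenomeLayout.uniform(2, 2)


@pytest.fixture
def layout13():
    return GenomeLayout.uniform(1, 3)


def random_profile(rng: np.random.Generator, layout: GenomeLayout, cap: int, name="p"):
    n = layout.n_segments
    return CopyNumberProfile(
        name, rng.integers(0, cap + 1, n), rng.integers(0, cap + 1, n)
    )
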