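import numpy as np
import pytest

from caseus import SeasonEffects, StudyDesign, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The 45 x 81 study-design dataset with block-missing FAME."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced design (17 complete + 6 partial, 18 variables) for fast fits."""
    design = StudyDesign(
        complete_counts=(6, 6, 5), partial_counts=(2, 2, 2), n_fame=10, n_minerals=8
    )
    return generate_dataset(design, SeasonEffects(latent_rank=3), seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
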