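import numpy as np
import pandas as pd
import pytest

import degnet


@pytest.fixture(scope="session")
def design4():
    """Default 4-condition, 2-replicate design (8 arrays)."""
    return degnet.make_design(2)


@pytest.fixture(scope="session")
def design2():
    """Minimal two-condition design for single-contrast tests."""
    return degnet.make_design(2, ("MEF", "test"))


@pytest.fixture(scope="session")
def planted_dataset(design4):
    """Simulated dataset with 10% planted DEGs at effect 2.0, sd 0.25."""
    return degnet.simulate_dataset(
        1000, design4, deg_fraction=0.1, effect_size=2.0, noise_sd=0.25,
        seed=42,
    )


@pytest.fixture(scope="session")
def contrast_stats(planted_dataset, design4):
    """Per-contrast statistics tables for the planted dataset."""
    matrix, _ = planted_dataset
    return degnet.run_all_contrasts(matrix, design4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_matrix():
    return pd.DataFrame(
        {"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
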