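import numpy as np
import pandas as pd
import pytest

from heteropattern.data_model_io import CrossDesign, OmicsMatrix, SampleMeta
from heteropattern.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def zero_noise_study():
    """Small noise-free diallel study: every F1 level is exactly its
    pattern formula, so classification and profile identities are exact."""
    cfg = SimulationConfig(n_parents=4, n_features=200, noise_cv=0.0, seed=42)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_matrix():
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [10.0, 20.0, 30.0, 40.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3", "s4"])
    return OmicsMatrix(vals)


@pytest.fixture()
def toy_meta():
    return SampleMeta(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "genotype_id": ["A", "A", "B", "B"],
        "role": ["parent"] * 4,
        "stage": ["S1"] * 4,
        "replicate": [1, 2, 1, 2],
    }))


@pytest.fixture()
def two_parent_design():
    return CrossDesign(pd.DataFrame({
        "hybrid_id": ["AxB", "BxA"],
        "female_parent_id": ["A", "B"],
        "male_parent_id": ["B", "A"],
        "pooled_id": ["H_A_B", "H_A_B"],
    }))
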