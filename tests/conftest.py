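import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from tissuespec.biotypes import classify
from tissuespec.simulate import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config():
    """A fast 4-tissue configuration used by most simulation-backed tests."""
    return SimulationConfig(
        seed=1,
        n_tissues=4,
        n_sites=2,
        n_coding=500,
        n_noncoding=50,
        n_specific_per_tissue=10,
        module_size_per_tissue=20,
        specific_fold=8.0,
        replicate_noise_sd=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    expr, samples, annot, truth = simulate_expression(small_config)
    return expr, samples, classify(annot), truth


@pytest.fixture
def tiny_expr():
    """3 transcripts x 4 samples, two tissues with two replicates each."""
    expr = pd.DataFrame(
        np.array(
            [
                [10.0, 10.0, 1.0, 1.0],
                [0.5, 0.7, 0.5, 0.7],
                [0.0, 0.0, 3.0, 3.0],
            ]
        ),
        index=pd.Index(["t1", "t2", "t3"], name="transcript_id"),
        columns=["a_s1", "a_s2", "b_s1", "b_s2"],
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["a_s1", "a_s2", "b_s1", "b_s2"],
            "tissue": ["a", "a", "b", "b"],
            "site": ["s1", "s2", "s1", "s2"],
        }
    )
    return expr, samples
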