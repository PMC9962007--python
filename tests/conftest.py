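import numpy as np
import pytest

from ccsrt.pipeline import RunConfig, run_pipeline
from ccsrt.synthetic_data import generate_library, simulate_measurements


@pytest.fixture(scope="session")
def study_run():
    """One full synthetic study at the default conditions (n=200 standards,
    40 true / 30 decoy / 10 noise features, seed 1), shared across tests."""
    cfg = RunConfig(out_dir="scratch/test_run", seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def small_library():
    """80-compound synthetic library + measured standards (seed 7)."""
    library, truth = generate_library(80, seed=7)
    measured = simulate_measurements(library, truth, seed=8)
    return library, truth, measured


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
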