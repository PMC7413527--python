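import numpy as np
import pytest

from fertresponse.mitscherlich import MitscherlichParams
from fertresponse.synth import GeneratorConfig, generate_trials

TRUTH_A = 40.0
TRUTH_E = (40.0, 25.0, 60.0)
TRUTH_R = (0.012, 0.025, 0.008)


@pytest.fixture(scope="session")
def truth_params() -> MitscherlichParams:
    """Constant (covariate-free) ground-truth surface parameters."""
    return MitscherlichParams.constant(A=TRUTH_A, E=TRUTH_E, R=TRUTH_R)


@pytest.fixture(scope="session")
def noiseless_dataset(truth_params):
    """Small noiseless mixed-type trial set generated from known truth."""
    cfg = GeneratorConfig(n_trials=8, blocks_per_trial=3, treatments_per_trial=5,
                          trial_type="mixed", noise_sd=0.0, block_sd=0.0, seed=11)
    return generate_trials(cfg, ground_truth_params=truth_params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
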