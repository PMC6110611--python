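import numpy as np
import pytest
from hypothesis import settings

# one deterministic, example-shrinking-free profile for the whole suite
settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True, print_blob=False)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def e6_theta():
    """Subject-averaged fitted parameters of one of the color experiments."""
    return {"beta": 0.61, "lambda": 8.8e-3, "tau": 7.4}


@pytest.fixture(scope="session")
def e6_params(e6_theta):
    from rrwm import CostSpec, ModelParams
    return ModelParams(lambda_=e6_theta["lambda"], tau=e6_theta["tau"],
                       cost=CostSpec("power", beta=e6_theta["beta"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
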