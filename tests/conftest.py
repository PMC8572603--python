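import numpy as np
import pytest

from elbownms import (
    ActivationSet,
    baseline_params,
    default_params,
    planned_trajectory,
    synthetic_activations,
)


@pytest.fixture(scope="session")
def model():
    return default_params()


@pytest.fixture(scope="session")
def baseline():
    return baseline_params()


@pytest.fixture(scope="session")
def fp(model):
    return model.formula


@pytest.fixture(scope="session")
def trajectory():
    return planned_trajectory()


@pytest.fixture(scope="session")
def activations(trajectory, model):
    return synthetic_activations(trajectory, profiles=model.profiles, seed=7)


@pytest.fixture()
def zero_activations(trajectory, model):
    import pandas as pd

    data = pd.DataFrame({name: np.zeros(len(trajectory)) for name in model.names})
    return ActivationSet(t=trajectory.t, data=data)
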