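import numpy as np
import pytest

from intertemporal import (
    AgentSpec,
    ModelParams,
    generate_trials,
    simulate_choices,
)


@pytest.fixture(scope="session")
def design84():
    """A standard 84-trial, two-run task design."""
    return generate_trials(84, 2, seed=1)


@pytest.fixture(scope="session")
def hyperbolic_agent():
    params = ModelParams(
        model_name="hyperbolic", k=float(np.exp(-4.6)), beta_temp=3.74
    )
    return AgentSpec(model_name="hyperbolic", params=params, seed=7)


@pytest.fixture(scope="session")
def hyperbolic_records(design84, hyperbolic_agent):
    return simulate_choices(design84, hyperbolic_agent)
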