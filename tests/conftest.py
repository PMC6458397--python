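import numpy as np
import pytest

from sociallearn import AgentMemory, LearningParameters, StimulusElement


@pytest.fixture
def elements():
    return {
        "X": StimulusElement("X", 0.0),
        "Y": StimulusElement("Y", 0.0),
        "S_reward": StimulusElement("S_reward", 25.0),
        "S_neutral": StimulusElement("S_neutral", 0.0),
    }


@pytest.fixture
def memory(elements):
    """A blank two-behaviour memory over the shared element set."""
    return AgentMemory(elements=elements, behaviours=("B", "other"),
                       params=LearningParameters())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
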