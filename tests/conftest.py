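import numpy as np
import pytest

from residual_eegnet.data_model import EEGEpoch, TaskLabel
from residual_eegnet.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_epoch(rng):
    return EEGEpoch(data=rng.normal(size=(64, 720)), subject_id=1,
                    session_id=1, label=TaskLabel.REST)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """4 subjects x 4 trials/class with planted LEFT/RIGHT channels."""
    spec = SyntheticSpec(
        n_subjects=4,
        trials_per_class_per_subject=4,
        planted_channels={TaskLabel.LEFT: frozenset({8}),
                          TaskLabel.RIGHT: frozenset({12})},
        effect_amplitude=0.8,
        seed=11,
    )
    return generate_dataset(spec)
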