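from dataclasses import replace

import numpy as np
import pytest

from dusqa.pipeline import build_dataset
from dusqa.synthetic import SynthConfig, gen_dataset


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def synth_recordings(synth_config):
    """Default study-condition dataset: 10 recordings per class, 25 segments
    each, so every class contributes 210 maximally-overlapping windows."""
    return gen_dataset(50, None, synth_config, seed=1)


@pytest.fixture(scope="session")
def full_dataset(synth_config):
    """Scalograms and labels for the learnability dataset.

    Annotator noise is disabled so every class keeps all 210 windows
    (unanimity classes lose roughly half their windows under the default
    5% flip rate, which would leave fewer than 200 per class)."""
    cfg = replace(synth_config, annotator_flip=0.0, annotator_unsure=0.0)
    return build_dataset(gen_dataset(50, None, cfg, seed=1))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
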