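import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

import phasicpain as pp
from phasicpain.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def strong_dataset():
    """Small cohort in the separable regime: every pain stimulus produces a
    facial response and everyone is expressive."""
    cfg = SyntheticConfig(
        response_prob_means=(1.0, 1.0, 1.0),
        response_prob_subject_sd=0.0,
        nonresponder_frac=0.0,
        expressiveness_sigma=0.2,
    )
    return pp.generate_dataset(12, 2, seed=42, config=cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small cohort under the default study-like conditions (about 40% of
    pain samples without any facial response)."""
    return pp.generate_dataset(10, 2, seed=7)
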