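import numpy as np
import pytest

from wordbyword.lexicon import default_lexicon
from wordbyword.synthetic_session import ArtifactRates, SynthParams
from wordbyword.trial_design import DesignSpec, build_trial_plan


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon(240, seed=0)


@pytest.fixture(scope="session")
def paper_plan(lexicon):
    """The published design: 240 trials, 75/25 congruency, 2:1 split."""
    return build_trial_plan(DesignSpec(), lexicon, seed=7)


@pytest.fixture(scope="session")
def small_plan(lexicon):
    return build_trial_plan(DesignSpec(n_trials=12), lexicon, seed=3)


@pytest.fixture
def clean_params():
    """Generator settings without artifacts (lip smacks, blinks, EMG)."""
    return SynthParams(
        artifacts=ArtifactRates(
            lip_smack_prob=0.0, blink_rate_per_min=0.0, jaw_emg_uv=0.0
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
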