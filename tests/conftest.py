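import numpy as np
import pytest
from hypothesis import settings

# property tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ichnostats import synthetic as syn
from ichnostats.regions import REGIONS


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def flat_means():
    """A morph with uniform 5 mm depth means in every region."""
    return {r: 5.0 for r in REGIONS}


@pytest.fixture
def small_dataset():
    """Two-morph depth table small enough for hand inspection."""
    morphs = [
        syn.default_reference_morph(n_subjects=8, n_tracks=3),
        syn.default_outgroup_morph(n_subjects=2, n_tracks=4),
    ]
    return syn.generate_depth_dataset(morphs, seed=42)
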