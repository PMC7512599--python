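import numpy as np
import pytest

from pdgain import CountHistogram, SyntheticSpec, synth_sequence


@pytest.fixture
def hist31():
    """Counts (3, 1) over bins 1, 2."""
    return CountHistogram.from_counts([3, 1])


@pytest.fixture
def hist32():
    """Counts (3, 2): the n_l = n_m + 1 zero-locus pair."""
    return CountHistogram.from_counts([3, 2])


@pytest.fixture
def tiny_pair():
    """The 2x2 one-changed-pixel fixture used across the docs and tests."""
    a = np.array([[0, 0], [0, 1]])
    b = np.array([[0, 0], [0, 0]])
    return a, b


@pytest.fixture
def moving_square_seq():
    spec = SyntheticSpec(kind="moving_square", frames=6, shape=(48, 48), displacement=(3, 0), seed=1)
    return spec, synth_sequence(spec)


@pytest.fixture
def focus_seq():
    spec = SyntheticSpec(kind="focus_stack", frames=21, shape=(48, 48), blur_step=0.5, seed=1)
    return spec, synth_sequence(spec)
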