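import numpy as np
import pytest

from ltrcks import LTRCSample, validate_sample
from ltrcks.simulation import get_scenario, simulate_ltrc_sample


@pytest.fixture
def toy_sample() -> LTRCSample:
    """Three records with one censored time: the hand-computed example."""
    return validate_sample([0, 1, 0], [2, 3, 4], [1, 1, 0], "toy")


@pytest.fixture
def disjoint_pair() -> list[LTRCSample]:
    """Untruncated uncensored groups {1,2} and {3,4}."""
    return [
        validate_sample([-1, -1], [1, 2], [1, 1], "a"),
        validate_sample([-1, -1], [3, 4], [1, 1], "b"),
    ]


def random_ltrc_samples(rng: np.random.Generator, k: int = 2, n: int = 40):
    """Random valid LTRC groups with truncation and moderate censoring."""
    out = []
    for j in range(k):
        spec = get_scenario(1).groups[0]
        out.append(simulate_ltrc_sample(spec, n, rng, label=j))
    return out


@pytest.fixture
def scenario1_group():
    return get_scenario(1).groups[0]
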