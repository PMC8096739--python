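import numpy as np
import pytest

from imagery_rsa import Condition, StimulusItem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_conditions(n, category="building", domain="imagery",
                    quadrant=None, experiment=3):
    """n distinct conditions of one category/domain for small fixtures."""
    items = [StimulusItem(item_id=f"{category}:x{i}", label=f"x{i}",
                          category=category, quadrant=quadrant,
                          experiment=experiment)
             for i in range(n)]
    return [Condition(item=i, domain=domain) for i in items]


@pytest.fixture
def two_conditions():
    return make_conditions(2)
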