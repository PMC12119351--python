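import numpy as np
import pytest

from hedonifeed.motifs import ArenaConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def open_field_arena():
    """50-cm chamber with corner cups: room for all locomotion classes."""
    return ArenaConfig(
        chamber_size_cm=(50.0, 50.0),
        cup_food_xy=(5.0, 5.0),
        cup_empty_xy=(45.0, 45.0),
    )


@pytest.fixture
def feeding_arena():
    """The 25-cm feeding-chamber geometry."""
    return ArenaConfig(
        chamber_size_cm=(25.0, 25.0),
        cup_food_xy=(4.0, 4.0),
        cup_empty_xy=(21.0, 21.0),
    )
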