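import numpy as np
import pytest

from fire_dynamics import BurnEvent, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_scene():
    """16x16, 6-year scene with two disjoint planted scars."""
    return SceneConfig(
        grid_rows=16, grid_cols=16, years=tuple(range(2001, 2007)), seed=7,
        burn_events=(
            BurnEvent(2003, 2, 2, 4, 4, "MLS", 0.30),
            BurnEvent(2003, 9, 9, 5, 3, "MHS", 0.50),
            BurnEvent(2005, 4, 10, 3, 3, "HS", 0.70),
        ),
    )
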