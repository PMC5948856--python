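import sys
from pathlib import Path

import numpy as np
import pytest

from pestgrid import SimConfig, World, get_strategy, initialize

sys.path.insert(0, str(Path(__file__).parent))


class QueuedRNG:
    """Deterministic stand-in for a Generator: returns queued draws."""

    def __init__(self, integers=(), floats=()):
        self._integers = list(integers)
        self._floats = list(floats)

    def integers(self, low, high):
        return self._integers.pop(0)

    def random(self):
        return self._floats.pop(0)


@pytest.fixture
def queued_rng():
    return QueuedRNG


def make_world(columns=4, rows=4, strategy="neighbor", **kwargs):
    """Empty world (no bugs) for direct capability-level tests."""
    cfg = SimConfig(
        columns=columns,
        rows=rows,
        initial_affected_areas=0,
        p_appear=0.0,
        strategy=strategy,
        **kwargs,
    )
    return initialize(cfg, np.random.default_rng(0))


@pytest.fixture
def empty_world():
    return make_world()
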