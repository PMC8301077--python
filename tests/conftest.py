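import numpy as np
import pytest

from cagerank.ethogram import (
    Behavior,
    BehaviorEvent,
    CageMeta,
    SamplingScheme,
    Strain,
)


@pytest.fixture
def meta3():
    return CageMeta(
        cage_id="K1",
        strain=Strain.SJL,
        group_size=3,
        mouse_ids=("A", "B", "C"),
        batch=1,
    )


@pytest.fixture
def meta5():
    return CageMeta(
        cage_id="K2",
        strain=Strain.ALBINO_B6,
        group_size=5,
        mouse_ids=("A", "B", "C", "D", "E"),
        batch=1,
    )


@pytest.fixture
def scheme():
    return SamplingScheme(window_s=60.0, period_s=300.0, days=(2, 7))


@pytest.fixture
def simple_events():
    """A tiny validated stream: 2 mediated + 1 escalated + 1 submission +
    1 allogroom + 1 investigation, time-sorted."""
    return [
        BehaviorEvent(2, 10.0, "A", "B", Behavior.MEDIATED_AGGRESSION),
        BehaviorEvent(2, 20.0, "A", "C", Behavior.ESCALATED_AGGRESSION),
        BehaviorEvent(2, 25.0, "C", "A", Behavior.SUBMISSION),
        BehaviorEvent(2, 40.0, "B", "C", Behavior.ALLOGROOM),
        BehaviorEvent(7, 15.0, "A", "B", Behavior.MEDIATED_AGGRESSION),
        BehaviorEvent(7, 30.0, "C", "B", Behavior.INVESTIGATION),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
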