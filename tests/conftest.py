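import numpy as np
import pytest

from eventemb.synthetic import make_chain, make_planted_communities, make_random_events
from eventemb.temporal_io import Event, TemporalNetwork


@pytest.fixture
def chain5():
    tn, sizes = make_chain(5)
    return tn, sizes


@pytest.fixture
def small_net():
    """Hand-built network exercising shared links, co-occurrence and gaps."""
    events = [
        Event(0, "a", "b"),
        Event(0, "b", "c"),
        Event(1, "b", "c"),
        Event(2, "a", "b"),
        Event(2, "b", "c"),
        Event(3, "c", "d"),
        Event(5, "a", "b"),
    ]
    return TemporalNetwork(events)


@pytest.fixture
def random_net():
    return make_random_events(8, 30, 12, seed=42)


@pytest.fixture
def planted():
    return make_planted_communities(2, 10, 12, p_in=0.25, p_out=0.01, seed=7)
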