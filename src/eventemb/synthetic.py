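"""Synthetic temporal networks with known ground truth.

Generators emit the truth (labels, expected epidemic sizes) alongside the
data so tests never re-derive it from the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np

from eventemb.temporal_io import Event, TemporalNetwork

__all__ = [
    "make_chain",
    "make_planted_communities",
    "make_random_events",
    "PlantedNetwork",
]


def make_chain(n_nodes: int) -> Tuple[TemporalNetwork, Dict[Event, int]]:
    """Path of events (v_k, v_{k+1}, k) for k = 0..n-2.

    Returns the network plus the exact epidemic size per seed: seeding at
    event k infects nodes v_k..v_{n-1}, i.e. size n - k.
    """
    if n_nodes < 2:
        raise ValueError("a chain needs at least 2 nodes")
    width = len(str(n_nodes - 1))
    names = [f"v{idx:0{width}d}" for idx in range(n_nodes)]
    events = [Event(k, names[k], names[k + 1]) for k in range(n_nodes - 1)]
    sizes = {e: n_nodes - k for k, e in enumerate(events)}
    return TemporalNetwork(events), sizes


@dataclass
class PlantedNetwork:
    network: TemporalNetwork
    event_labels: Dict[Event, int]  # ground-truth group per event
    node_labels: Dict[str, int]  # ground-truth group per node
    windows: List[Tuple[int, int]]  # [start, end) snapshot window per group


def make_planted_communities(
    n_groups: int,
    nodes_per_group: int,
    snapshots_per_group: int,
    p_in: float,
    p_out: float = 0.0,
    seed: Optional[int] = None,
) -> PlantedNetwork:
    """Groups of nodes, each preferentially active in its own consecutive
    time window.

    Within group g's window, every within-group pair fires per snapshot
    with probability ``p_in``; every cross-group pair fires with probability
    ``p_out`` throughout the whole horizon.  The ground-truth label of an
    event is the group of the window it falls in (cross-group events get the
    label of the enclosing window).
    """
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(n_groups * nodes_per_group - 1))
    nodes = [[f"n{g * nodes_per_group + k:0{width}d}" for k in range(nodes_per_group)]
             for g in range(n_groups)]
    node_labels = {u: g for g, grp in enumerate(nodes) for u in grp}
    windows = [
        (g * snapshots_per_group, (g + 1) * snapshots_per_group) for g in range(n_groups)
    ]
    horizon = n_groups * snapshots_per_group

    events: List[Event] = []
    labels: Dict[Event, int] = {}
    for g, (start, end) in enumerate(windows):
        for t in range(start, end):
            for u, v in combinations(nodes[g], 2):
                if rng.random() < p_in:
                    e = Event(t, u, v)
                    events.append(e)
                    labels[e] = g
    if p_out > 0:
        cross = [
            (u, v)
            for ga, gb in combinations(range(n_groups), 2)
            for u in nodes[ga]
            for v in nodes[gb]
        ]
        for t in range(horizon):
            window_of_t = min(t // snapshots_per_group, n_groups - 1)
            for u, v in cross:
                if rng.random() < p_out:
                    e = Event(t, u, v)
                    if e not in labels:
                        events.append(e)
                        labels[e] = window_of_t
    tn = TemporalNetwork(events, nodes={u for grp in nodes for u in grp})
    labels = {e: labels[e] for e in tn.events}
    return PlantedNetwork(tn, labels, node_labels, windows)


def make_random_events(
    n_nodes: int, n_events: int, horizon: int, seed: Optional[int] = None
) -> TemporalNetwork:
    """Uniform random distinct (pair, snapshot) draws; no self events."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    n_slots = n_nodes * (n_nodes - 1) // 2 * horizon
    if n_events > n_slots:
        raise ValueError(f"cannot place {n_events} distinct events in {n_slots} slots")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes - 1))
    names = [f"u{idx:0{width}d}" for idx in range(n_nodes)]
    pairs = list(combinations(names, 2))
    slot_ids = rng.choice(n_slots, size=n_events, replace=False)
    events = [
        Event(int(sid) // len(pairs), *pairs[int(sid) % len(pairs)]) for sid in slot_ids
    ]
    return TemporalNetwork(events, nodes=set(names))
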