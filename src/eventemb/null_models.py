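"""Randomized reference models: shufflings that destroy chosen correlations.

* ``snapshot_shuffle`` permutes event timestamps across events — structure
  and global activity profile survive, temporal order does not.
* ``timeline_shuffle`` permutes whole per-link timelines among the links of
  the aggregated graph — structure and timeline contents survive, the
  link-to-timeline matching does not.
* ``link_shuffle`` redraws the static graph uniformly among simple graphs
  with the same node count and link count (G(n, m)) and reassigns the
  original timelines to the new links by a random bijection — only the
  timeline contents (local temporal correlations) survive.

All three return a valid temporal network accepted by every downstream
stage.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from eventemb.temporal_io import Event, TemporalNetwork, aggregate

__all__ = ["snapshot_shuffle", "timeline_shuffle", "link_shuffle"]


def snapshot_shuffle(tn: TemporalNetwork, seed: Optional[int] = None) -> TemporalNetwork:
    """Randomly permute the multiset of timestamps across events."""
    rng = np.random.default_rng(seed)
    times = np.array([e.t for e in tn.events])
    # a permutation may hand the same (link, t) to two events when the
    # timestamp multiset has repeats; redraw until the result is collision-free
    for _ in range(1000):
        perm = rng.permutation(len(times))
        events = [Event(int(times[perm[k]]), e.i, e.j) for k, e in enumerate(tn.events)]
        if len(set(events)) == len(events):
            return TemporalNetwork(
                events, delta_t_seconds=tn.delta_t_seconds, nodes=set(tn.nodes)
            )
    raise RuntimeError("could not find a collision-free timestamp permutation")


def timeline_shuffle(tn: TemporalNetwork, seed: Optional[int] = None) -> TemporalNetwork:
    """Randomly permute entire timelines among the links of the static graph."""
    rng = np.random.default_rng(seed)
    g = aggregate(tn)
    links = sorted(g.timelines)
    timelines = [g.timelines[l] for l in links]
    perm = rng.permutation(len(links))
    events = [
        Event(t, *links[k])
        for k in range(len(links))
        for t in timelines[perm[k]]
    ]
    return TemporalNetwork(events, delta_t_seconds=tn.delta_t_seconds, nodes=set(tn.nodes))


def link_shuffle(tn: TemporalNetwork, seed: Optional[int] = None) -> TemporalNetwork:
    """Replace the static graph by a uniform G(n, m) draw and reattach the
    original timelines to the new links by a random bijection."""
    rng = np.random.default_rng(seed)
    g = aggregate(tn)
    nodes = sorted(tn.nodes)
    n = len(nodes)
    m = len(g.timelines)
    if m > n * (n - 1) // 2:
        raise ValueError("more links than a simple graph admits")
    # uniform sample of m distinct unordered pairs out of C(n, 2)
    rows, cols = np.triu_indices(n, k=1)
    pair_ids = rng.choice(len(rows), size=m, replace=False)
    new_links: List[tuple] = [
        (nodes[rows[pid]], nodes[cols[pid]]) for pid in sorted(pair_ids.tolist())
    ]
    timelines = [g.timelines[l] for l in sorted(g.timelines)]
    perm = rng.permutation(m)
    events = [
        Event(t, *new_links[k])
        for k in range(m)
        for t in timelines[perm[k]]
    ]
    return TemporalNetwork(events, delta_t_seconds=tn.delta_t_seconds, nodes=set(tn.nodes))
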