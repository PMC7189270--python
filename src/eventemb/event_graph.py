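"""The weighted event graph: a directed acyclic higher-order view in which
events are nodes and adjacent (node-sharing, time-ordered) events are linked.

Each edge e1 -> e2 carries two weights:

* ``w_path = 1 / (1 + (t2 - t1))`` — rewards temporally close, potentially
  causal pairs;
* ``w_co`` — the number of snapshots in which the two underlying static
  links fire simultaneously (identical for every event pair on the same
  link pair).

For a given source event and a given destination link only the *earliest*
admissible successor is kept.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

from eventemb.temporal_io import Event, StaticGraph, TemporalNetwork, aggregate, links_adjacent

__all__ = [
    "EventGraphEdge",
    "WeightedEventGraph",
    "build_event_graph",
    "compute_w_path",
    "compute_w_co",
]

Link = Tuple[str, str]
Neighbor = Tuple[Event, float, int]


def compute_w_path(t1: int, t2: int) -> float:
    """Temporal-proximity weight 1/(1 + (t2 - t1)); requires t2 > t1."""
    if t2 <= t1:
        raise ValueError(f"w_path needs strictly ordered times, got {t1} >= {t2}")
    return 1.0 / (1.0 + (t2 - t1))


def compute_w_co(g: StaticGraph, l1: Link, l2: Link) -> int:
    """Number of snapshots in which both links have an event.

    For l1 == l2 this degenerates to the link's own timeline length (the
    intersection of a timestamp set with itself).
    """
    if not links_adjacent(l1, l2):
        raise ValueError(f"links {l1} and {l2} share no node")
    s1 = set(g.timeline(*l1))
    if l1 == l2:
        return len(s1)
    return len(s1 & set(g.timeline(*l2)))


@dataclass(frozen=True)
class EventGraphEdge:
    src: Event
    dst: Event
    w_path: float
    w_co: int


@dataclass
class WeightedEventGraph:
    """Adjacency-indexed container of event-graph edges.

    ``delta_t`` is the adjacency horizon in snapshot units; ``None`` means
    unrestricted (the full observation period).
    """

    events: List[Event]
    delta_t: Optional[int]
    _succ: Dict[Event, List[Neighbor]] = field(default_factory=dict)
    _pred: Dict[Event, List[Neighbor]] = field(default_factory=dict)

    def add_edge(self, src: Event, dst: Event, w_path: float, w_co: int) -> None:
        self._succ.setdefault(src, []).append((dst, w_path, w_co))
        self._pred.setdefault(dst, []).append((src, w_path, w_co))

    def successors(self, e: Event) -> List[Neighbor]:
        self._check(e)
        return list(self._succ.get(e, []))

    def predecessors(self, e: Event) -> List[Neighbor]:
        self._check(e)
        return list(self._pred.get(e, []))

    def neighborhood(self, e: Event, mode: str = "combined") -> List[Neighbor]:
        """First neighbors of ``e`` per sampling mode, in deterministic order."""
        if mode == "combined":
            nb = self.predecessors(e) + self.successors(e)
        elif mode == "predecessors_only":
            nb = self.predecessors(e)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        nb.sort(key=lambda item: item[0])
        return nb

    @property
    def edges(self) -> List[EventGraphEdge]:
        return [
            EventGraphEdge(src, dst, wp, wc)
            for src, nbrs in sorted(self._succ.items())
            for dst, wp, wc in sorted(nbrs)
        ]

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self._succ.values())

    def _check(self, e: Event) -> None:
        if e not in self._event_set:
            raise KeyError(f"event {e.token} not in graph")

    def __post_init__(self) -> None:
        self._event_set = set(self.events)

    def write_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for edge in self.edges:
                fh.write(
                    f"{edge.src.token}\t{edge.dst.token}\t{edge.w_path:.10g}\t{edge.w_co}\n"
                )


def build_event_graph(
    tn: TemporalNetwork, delta_t: Union[int, str, None] = "full"
) -> WeightedEventGraph:
    """Construct the weighted event graph of ``tn``.

    For every event e1 = (i, j, t1) and every static link (k, l) adjacent to
    (i, j) — including (i, j) itself — an edge e1 -> e2 is added where e2 is
    the earliest event on (k, l) with t1 < t2 <= t1 + delta_t, if any.
    Same-snapshot events are never adjacent; their relation enters only
    through w_co.
    """
    if delta_t in ("full", None):
        horizon: Optional[int] = None
    else:
        horizon = int(delta_t)
        if horizon < 1:
            raise ValueError("delta_t must be >= 1 or 'full'")

    g = aggregate(tn)
    graph = WeightedEventGraph(events=list(tn.events), delta_t=horizon)
    if len(tn.events) < 2:
        return graph

    # Links incident to each node, and per-link event lookup keyed by sorted
    # timeline position, so the earliest admissible successor is a bisect.
    links_of_node: Dict[str, List[Link]] = {}
    for link in g.timelines:
        links_of_node.setdefault(link[0], []).append(link)
        links_of_node.setdefault(link[1], []).append(link)

    w_co_cache: Dict[Tuple[Link, Link], int] = {}

    def w_co_of(l1: Link, l2: Link) -> int:
        key = (l1, l2) if l1 <= l2 else (l2, l1)
        if key not in w_co_cache:
            w_co_cache[key] = compute_w_co(g, key[0], key[1])
        return w_co_cache[key]

    for e1 in tn.events:
        seen_links = set()
        for node in e1.link:
            for l2 in links_of_node[node]:
                if l2 in seen_links:
                    continue
                seen_links.add(l2)
                timeline = g.timelines[l2]
                pos = bisect_right(timeline, e1.t)
                if pos == len(timeline):
                    continue
                t2 = timeline[pos]
                if horizon is not None and t2 - e1.t > horizon:
                    continue
                e2 = Event(t2, *l2)
                graph.add_edge(e1, e2, compute_w_path(e1.t, t2), w_co_of(e1.link, l2))
    return graph
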