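"""Reading, writing, validating and aggregating snapshot-resolved event lists.

The on-disk dialect is a plain whitespace/tab-separated file with one event
per line, either ``t i j`` or ``i j t``.  Timestamps are rebased so the
earliest event sits at snapshot 0 and are expressed in integer snapshot
units (raw seconds divided by the snapshot width, 20 s by default).
Lines starting with ``#`` are comments; extra trailing columns are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

__all__ = [
    "Event",
    "TemporalNetwork",
    "StaticGraph",
    "read_event_list",
    "write_event_list",
    "aggregate",
    "ValidationError",
    "ParseError",
]

Link = Tuple[str, str]


class ValidationError(ValueError):
    """Raised when an event list violates a structural invariant."""


class ParseError(ValueError):
    """Raised on malformed input lines; carries the offending line number."""


@dataclass(frozen=True, order=True)
class Event:
    """An undirected timestamped interaction, canonically stored with i < j.

    Ordering is (t, i, j) so that sorted event collections are in
    chronological, deterministic order.
    """

    t: int
    i: str
    j: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValidationError(f"self event forbidden: ({self.i}, {self.j}, {self.t})")
        if self.t < 0:
            raise ValidationError(f"negative timestamp: {self.t}")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def link(self) -> Link:
        return (self.i, self.j)

    @property
    def token(self) -> str:
        """Stable string identifier used in corpora and exports."""
        return f"{self.i}|{self.j}|{self.t}"

    @classmethod
    def from_token(cls, token: str) -> "Event":
        i, j, t = token.rsplit("|", 2)
        return cls(int(t), i, j)


@dataclass
class TemporalNetwork:
    """A validated, canonically ordered sequence of events.

    ``delta_t_seconds`` is metadata only (the wall-clock snapshot width);
    all timestamps are integer snapshot indices.
    """

    events: List[Event]
    delta_t_seconds: float = 20.0
    nodes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for e in sorted(self.events):
            if e not in seen:
                seen.add(e)
                deduped.append(e)
        self.events = deduped
        derived = {n for e in self.events for n in (e.i, e.j)}
        if self.nodes:
            if not derived <= self.nodes:
                raise ValidationError("events reference nodes outside the declared node set")
            self.nodes = set(self.nodes) | derived
        else:
            self.nodes = derived
        if self.delta_t_seconds <= 0:
            raise ValidationError("snapshot width must be positive")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalNetwork):
            return NotImplemented
        return self.events == other.events and self.nodes == other.nodes

    @property
    def horizon(self) -> int:
        """tau: spread between the earliest and latest snapshot."""
        if not self.events:
            return 0
        return self.events[-1].t - self.events[0].t

    def rebased(self) -> "TemporalNetwork":
        """Shift timestamps so the earliest event is at snapshot 0."""
        if not self.events or self.events[0].t == 0:
            return self
        t0 = self.events[0].t
        return TemporalNetwork(
            [Event(e.t - t0, e.i, e.j) for e in self.events],
            delta_t_seconds=self.delta_t_seconds,
            nodes=set(self.nodes),
        )


@dataclass
class StaticGraph:
    """Time-aggregated view: links that ever fired, with per-link timelines."""

    nodes: Set[str]
    timelines: Dict[Link, List[int]]

    @property
    def links(self) -> Set[Link]:
        return set(self.timelines)

    def timeline(self, i: str, j: str) -> List[int]:
        key = (i, j) if i < j else (j, i)
        return self.timelines[key]

    def neighbors(self, node: str) -> Set[str]:
        out = set()
        for a, b in self.timelines:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out


def read_event_list(
    path,
    column_order: str = "t_i_j",
    snapshot_seconds: float = 20.0,
    timestamps_in_seconds: bool = False,
) -> TemporalNetwork:
    """Parse a whitespace-separated event list into a `TemporalNetwork`.

    Parameters
    ----------
    path:
        File to read. Lines beginning with ``#`` and blank lines are skipped.
    column_order:
        ``"t_i_j"`` (timestamp first) or ``"i_j_t"``.
    snapshot_seconds:
        Snapshot width used to convert raw-second timestamps to snapshot
        units when ``timestamps_in_seconds`` is set, and recorded as
        metadata either way.
    timestamps_in_seconds:
        If true, raw timestamps are divided by ``snapshot_seconds`` (after
        rebasing to the earliest timestamp) instead of being taken as
        snapshot indices directly.
    """
    if column_order not in ("t_i_j", "i_j_t"):
        raise ValueError(f"unknown column order {column_order!r}")
    raw: List[Tuple[float, str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"line {lineno}: expected >=3 fields, got {len(parts)}")
            if column_order == "t_i_j":
                t_raw, i, j = parts[0], parts[1], parts[2]
            else:
                i, j, t_raw = parts[0], parts[1], parts[2]
            try:
                t_val = float(t_raw)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad timestamp {t_raw!r}") from exc
            if i == j:
                raise ValidationError(f"line {lineno}: self event {i!r}")
            raw.append((t_val, i, j))
    if not raw:
        raise ParseError(f"{path}: no events found")
    t0 = min(t for t, _, _ in raw)
    events = []
    for t_val, i, j in raw:
        rel = t_val - t0
        snap = rel / snapshot_seconds if timestamps_in_seconds else rel
        snap_int = int(round(snap))
        if not math.isclose(snap, snap_int, abs_tol=1e-9):
            raise ParseError(
                f"timestamp {t_val} is not a whole number of snapshots "
                f"(width {snapshot_seconds})"
            )
        events.append(Event(snap_int, i, j))
    return TemporalNetwork(events, delta_t_seconds=snapshot_seconds).rebased()


def write_event_list(tn: TemporalNetwork, path, column_order: str = "t_i_j") -> None:
    """Write in the canonical (t, i, j) order; round-trips with `read_event_list`."""
    if column_order not in ("t_i_j", "i_j_t"):
        raise ValueError(f"unknown column order {column_order!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for e in tn.events:
            if column_order == "t_i_j":
                fh.write(f"{e.t}\t{e.i}\t{e.j}\n")
            else:
                fh.write(f"{e.i}\t{e.j}\t{e.t}\n")


def aggregate(tn: TemporalNetwork) -> StaticGraph:
    """Collapse time: one link per node pair that ever interacted, with its
    sorted timeline of snapshots."""
    timelines: Dict[Link, List[int]] = {}
    for e in tn.events:
        timelines.setdefault(e.link, []).append(e.t)
    for tl in timelines.values():
        tl.sort()
    return StaticGraph(nodes=set(tn.nodes), timelines=timelines)


def links_adjacent(l1: Link, l2: Link) -> bool:
    """Two static links are adjacent when they share at least one endpoint
    (a link is trivially adjacent to itself)."""
    return bool(set(l1) & set(l2))
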