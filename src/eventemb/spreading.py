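"""Deterministic SI epidemics seeded at single events.

Transmission probability is 1 and there is no recovery, so the final
epidemic size is a pure function of the network and the seed event.  Both
endpoints of the seed become infected at the seed's snapshot; events
simultaneous with the seed do not transmit.  Within each later snapshot,
events are iterated to a fixed point, so infection covers the connected
component of the snapshot graph that touches an infected node.
"""

from __future__ import annotations

from typing import Dict, List

from eventemb.temporal_io import Event, TemporalNetwork

__all__ = ["SIOutcome", "simulate_si", "epidemic_sizes_all_seeds"]


class SIOutcome:
    __slots__ = ("seed", "final_size")

    def __init__(self, seed: Event, final_size: int):
        self.seed = seed
        self.final_size = final_size

    def __repr__(self) -> str:
        return f"SIOutcome(seed={self.seed.token}, final_size={self.final_size})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SIOutcome)
            and self.seed == other.seed
            and self.final_size == other.final_size
        )


def _snapshots_after(tn: TemporalNetwork, t0: int) -> List[List[Event]]:
    by_t: Dict[int, List[Event]] = {}
    for e in tn.events:
        if e.t > t0:
            by_t.setdefault(e.t, []).append(e)
    return [by_t[t] for t in sorted(by_t)]


def simulate_si(
    tn: TemporalNetwork, seed: Event, intra_snapshot_chains: bool = True
) -> SIOutcome:
    """Run the deterministic SI process from ``seed``.

    With ``intra_snapshot_chains`` (default) a snapshot is treated as an
    undirected graph and infection reaches its full connected component
    containing infected nodes; otherwise each event transmits at most once
    per snapshot pass.
    """
    if seed not in set(tn.events):
        raise KeyError(f"seed event {seed.token} not in network")
    infected = {seed.i, seed.j}
    for snapshot in _snapshots_after(tn, seed.t):
        if intra_snapshot_chains:
            changed = True
            while changed:
                changed = False
                for e in snapshot:
                    a, b = e.i in infected, e.j in infected
                    if a != b:
                        infected.add(e.i)
                        infected.add(e.j)
                        changed = True
        else:
            newly = set()
            for e in snapshot:
                a, b = e.i in infected, e.j in infected
                if a != b:
                    newly.add(e.j if a else e.i)
            infected |= newly
    return SIOutcome(seed, len(infected))


def epidemic_sizes_all_seeds(
    tn: TemporalNetwork, intra_snapshot_chains: bool = True
) -> Dict[Event, int]:
    """Final epidemic size for every event taken as seed."""
    return {
        e: simulate_si(tn, e, intra_snapshot_chains).final_size for e in tn.events
    }


def write_sizes(sizes: Dict[Event, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(sizes):
            fh.write(f"{e.token}\t{sizes[e]}\n")
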