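"""Per-event context environments sampled from the event-graph neighborhood.

The probability of drawing neighbor e_l for center e_k is

    p(e_l) = alpha * F(w_path(e_k, e_l)) + (1 - alpha) * F(w_co(e_k, e_l))

where F normalizes each weight type over the neighborhood. ``alpha`` mixes
temporal-path against co-occurrence information.  ``nb`` environments of
length ``s`` are drawn with replacement per event; events with empty
neighborhoods are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from eventemb.event_graph import WeightedEventGraph
from eventemb.temporal_io import Event

__all__ = ["SamplingConfig", "Environment", "sampling_probabilities", "sample_environments"]


@dataclass(frozen=True)
class SamplingConfig:
    alpha: float = 0.5
    nb: int = 10
    s: int = 10
    mode: str = "combined"  # or "predecessors_only"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.nb < 1 or self.s < 1:
            raise ValueError("nb and s must be positive")
        if self.mode not in ("combined", "predecessors_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Environment:
    """One Skip-Gram sentence: the center event followed by s context events."""

    center: Event
    context: List[Event]

    @property
    def tokens(self) -> List[str]:
        return [self.center.token] + [e.token for e in self.context]


def _normalize(weights: np.ndarray) -> np.ndarray:
    """F of the sampling rule; the all-zero case falls back to uniform
    (the normalization is undefined there, uniform is the least-informative
    completion)."""
    total = weights.sum()
    if total <= 0:
        return np.full(len(weights), 1.0 / len(weights))
    return weights / total


def sampling_probabilities(
    g: WeightedEventGraph, e_k: Event, alpha: float, mode: str = "combined"
) -> Dict[Event, float]:
    """Categorical distribution over the neighborhood of ``e_k``.

    Returns an empty mapping when the neighborhood is empty (the caller
    skips such events).
    """
    neighborhood = g.neighborhood(e_k, mode)
    if not neighborhood:
        return {}
    events = [nb[0] for nb in neighborhood]
    w_path = np.array([nb[1] for nb in neighborhood], dtype=float)
    w_co = np.array([nb[2] for nb in neighborhood], dtype=float)
    p = alpha * _normalize(w_path) + (1.0 - alpha) * _normalize(w_co)
    return dict(zip(events, p))


def sample_environments(
    g: WeightedEventGraph, cfg: SamplingConfig
) -> Tuple[List[Environment], List[Event]]:
    """Draw ``cfg.nb`` environments of length ``cfg.s`` for every event.

    Context events are drawn i.i.d. with replacement from the categorical
    distribution of `sampling_probabilities`.  Deterministic under a fixed
    seed; events are visited in canonical order.

    Returns
    -------
    (environments, skipped)
        ``skipped`` lists events with empty neighborhoods (these receive no
        environments and hence no embedding vector).
    """
    rng = np.random.default_rng(cfg.seed)
    environments: List[Environment] = []
    skipped: List[Event] = []
    for e_k in g.events:
        probs = sampling_probabilities(g, e_k, cfg.alpha, cfg.mode)
        if not probs:
            skipped.append(e_k)
            continue
        neighbors = list(probs.keys())
        p = np.fromiter(probs.values(), dtype=float, count=len(neighbors))
        p = p / p.sum()  # guard against float drift
        for _ in range(cfg.nb):
            idx = rng.choice(len(neighbors), size=cfg.s, replace=True, p=p)
            environments.append(Environment(e_k, [neighbors[i] for i in idx]))
    return environments, skipped


def write_corpus(environments: Sequence[Environment], path) -> None:
    """Plain-text corpus: one environment per line, center token first."""
    with open(path, "w", encoding="utf-8") as fh:
        for env in environments:
            fh.write(" ".join(env.tokens) + "\n")
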