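"""Entropy-based selection of the embedding dimension.

Rationale: past the optimal dimension, extra coordinates encode redundant
information, so pairwise euclidean distances stabilize across independent
training realisations.  For blocks of consecutive events we track, per event
pair, the spread of its distance over R realisations via a binned Shannon
entropy; the mean entropy versus dimension curve flattens out, and the
selected dimension is where the curve first crosses its best-fitting
horizontal line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from eventemb.embedding import SkipGramParams, train_embedding
from eventemb.event_graph import build_event_graph
from eventemb.sampling import SamplingConfig, sample_environments
from eventemb.temporal_io import TemporalNetwork

__all__ = [
    "EntropyCurve",
    "distance_entropy",
    "optimal_dimension",
    "pairwise_distance_tensor",
    "entropy_curve",
]

N_BINS = 10


@dataclass
class EntropyCurve:
    dimensions: List[int]
    mean_entropy: List[float]
    variance: List[float]
    optimal_d: int

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("d\tmean_H\tvar_H\n")
            for d, m, v in zip(self.dimensions, self.mean_entropy, self.variance):
                fh.write(f"{d}\t{m:.8g}\t{v:.8g}\n")


def distance_entropy(values: Sequence[float], bin_edges: np.ndarray) -> float:
    """Shannon entropy (natural log) of the histogram of ``values``.

    ``bin_edges`` must span the global distance range of the whole analysis
    so entropies are comparable across dimensions and realisations.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute entropy of no values")
    counts, _ = np.histogram(values, bins=bin_edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def optimal_dimension(dimensions: Sequence[int], mean_entropy: Sequence[float]) -> int:
    """Smallest d at which the curve first crosses its horizontal fit.

    The least-squares horizontal line is the mean of the curve; the curve is
    scanned left to right for the first sign change (or exact touch).  A
    curve that never crosses returns the last d with a warning.
    """
    if len(dimensions) < 3:
        raise ValueError("need at least 3 curve points")
    if len(dimensions) != len(mean_entropy):
        raise ValueError("curve lists misaligned")
    curve = np.asarray(mean_entropy, dtype=float)
    level = curve.mean()
    resid = curve - level
    if resid[0] == 0.0:
        return dimensions[0]
    for k in range(1, len(curve)):
        if resid[k] == 0.0 or (resid[k - 1] > 0) != (resid[k] > 0):
            return dimensions[k]
    warnings.warn("entropy curve never crosses its horizontal fit", stacklevel=2)
    return dimensions[-1]


def pairwise_distance_tensor(
    tn: TemporalNetwork,
    dims: Sequence[int],
    realisations: int = 10,
    sample_size: int = 1000,
    n_samples: int = 10,
    sampling_cfg: Optional[SamplingConfig] = None,
    train_params: Optional[SkipGramParams] = None,
    base_seed: int = 0,
    delta_t="full",
) -> Dict[int, List[np.ndarray]]:
    """Within-block pairwise distances for every (dimension, realisation).

    Trains ``realisations`` independent embeddings per dimension (fresh
    sampling and training seeds each), splits the embedded-event sequence
    into ``n_samples`` consecutive blocks of ``sample_size`` events, and
    returns ``{dim: [block arrays]}`` where each block array has shape
    (n_pairs_in_block, realisations).
    """
    sampling_cfg = sampling_cfg or SamplingConfig()
    train_params = train_params or SkipGramParams()
    graph = build_event_graph(tn, delta_t)
    # the skipped-event set depends only on the graph, so the embedded
    # vocabulary is identical across dimensions and realisations
    probe_cfg = replace(sampling_cfg, seed=0)
    _, skipped = sample_environments(graph, probe_cfg)
    skipped_set = set(skipped)
    embeddable = [e for e in tn.events if e not in skipped_set]

    n_total = len(embeddable)
    if n_total < 2:
        raise ValueError("fewer than 2 embeddable events")
    if n_total < sample_size:
        warnings.warn(
            f"only {n_total} embeddable events; shrinking blocks", stacklevel=2
        )
    blocks = []
    for b in range(n_samples):
        block = embeddable[b * sample_size : (b + 1) * sample_size]
        if len(block) >= 2:
            blocks.append(block)
    if not blocks:
        blocks = [embeddable]

    seed_rng = np.random.default_rng(base_seed)
    out: Dict[int, List[np.ndarray]] = {}
    for d in dims:
        per_block = [
            np.empty((len(block) * (len(block) - 1) // 2, realisations))
            for block in blocks
        ]
        for r in range(realisations):
            s_seed, t_seed = seed_rng.integers(0, 2**31 - 1, size=2)
            envs, _ = sample_environments(graph, replace(sampling_cfg, seed=int(s_seed)))
            emb = train_embedding(envs, d, replace(train_params, seed=int(t_seed)))
            for bi, block in enumerate(blocks):
                coords = np.stack([emb.vector(e) for e in block]).astype(float)
                per_block[bi][:, r] = pdist(coords)
        out[d] = per_block
    return out


def entropy_curve(distances: Dict[int, List[np.ndarray]]) -> EntropyCurve:
    """Reduce the distance tensor to mean entropy (and variance) per dimension.

    Bin edges are 10 equal-width bins spanning the global min/max over all
    dimensions, blocks and realisations.  Per event pair, entropy is taken
    over its distances across realisations; pair entropies are averaged
    within a block, and block values averaged (mean) / spread (variance)
    per dimension.
    """
    dims = sorted(distances)
    lo = min(arr.min() for d in dims for arr in distances[d])
    hi = max(arr.max() for d in dims for arr in distances[d])
    if hi <= lo:
        hi = lo + 1.0  # degenerate range: everything lands in one bin, H = 0
    edges = np.linspace(lo, hi, N_BINS + 1)

    mean_entropy, variance = [], []
    for d in dims:
        block_means = []
        for arr in distances[d]:
            # vectorized per-pair histogram over realisations
            idx = np.clip(np.searchsorted(edges, arr, side="right") - 1, 0, N_BINS - 1)
            counts = np.zeros((arr.shape[0], N_BINS))
            rows = np.repeat(np.arange(arr.shape[0]), arr.shape[1])
            np.add.at(counts, (rows, idx.ravel()), 1.0)
            p = counts / arr.shape[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
            block_means.append(float(h.mean()))
        mean_entropy.append(float(np.mean(block_means)))
        variance.append(float(np.var(block_means)))
    opt = optimal_dimension(dims, mean_entropy) if len(dims) >= 3 else dims[-1]
    return EntropyCurve(dims, mean_entropy, variance, opt)
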