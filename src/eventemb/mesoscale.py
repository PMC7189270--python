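"""Mesoscale structure via non-negative CP decomposition of the contact tensor.

The temporal network is a binary n x n x t tensor (node, node, snapshot).
It is factorized into r rank-one components with a node factor shared
between the two node modes (contacts are undirected), fitted by
multiplicative alternating updates.  Events are labeled with the component
whose reconstruction at their (link, time) entry is largest, and the rank is
selected with the core-consistency (CORCONDIA) diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from eventemb.temporal_io import Event, TemporalNetwork

__all__ = [
    "ContactTensor",
    "FactorModel",
    "build_tensor",
    "decompose",
    "assign_components",
    "core_consistency",
    "select_rank",
]


@dataclass
class ContactTensor:
    array: np.ndarray  # (n, n, t), binary, symmetric in the node modes
    node_index: Dict[str, int]

    @property
    def n_nodes(self) -> int:
        return self.array.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.array.shape[2]


@dataclass
class FactorModel:
    rank: int
    node_factors: np.ndarray  # (n, r), non-negative, unit-norm columns
    time_factors: np.ndarray  # (t, r), non-negative, carries component scale
    node_index: Dict[str, int]
    fit_residual: float  # relative reconstruction error


def build_tensor(tn: TemporalNetwork) -> ContactTensor:
    """Binary contact tensor with both (i, j, t) and (j, i, t) entries set."""
    nodes = sorted(tn.nodes)
    node_index = {u: k for k, u in enumerate(nodes)}
    n = len(nodes)
    t = tn.horizon + 1 if tn.events else 0
    arr = np.zeros((n, n, t), dtype=np.float64)
    for e in tn.events:
        a, b = node_index[e.i], node_index[e.j]
        arr[a, b, e.t] = 1.0
        arr[b, a, e.t] = 1.0
    return ContactTensor(arr, node_index)


def _reconstruct(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum("ic,jc,tc->ijt", A, A, C)


def decompose(
    tensor: ContactTensor,
    r: int,
    seed: Optional[int] = None,
    n_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 3,
) -> FactorModel:
    """Non-negative CP fit with the node factor shared across both node modes.

    Multiplicative alternating updates from ``n_restarts`` random starts;
    the best-fitting restart is kept.  Deterministic under ``seed``.
    """
    if r < 1:
        raise ValueError("rank must be >= 1")
    X = tensor.array
    n, _, t = X.shape
    if r > min(n, t):
        warnings.warn(f"rank {r} exceeds min tensor dimension {min(n, t)}", stacklevel=2)
    rng = np.random.default_rng(seed)
    norm_x = np.linalg.norm(X)
    eps = 1e-12

    best: Optional[Tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(max(1, n_restarts)):
        A = rng.random((n, r)) + 0.1
        C = rng.random((t, r)) + 0.1
        prev = np.inf
        for it in range(n_iter):
            AtA = A.T @ A
            num_a = np.einsum("ijt,jc,tc->ic", X, A, C)
            den_a = A @ (AtA * (C.T @ C)) + eps
            A *= num_a / den_a
            AtA = A.T @ A
            num_c = np.einsum("ijt,ic,jc->tc", X, A, A)
            den_c = C @ (AtA * AtA) + eps
            C *= num_c / den_c
            if it % 25 == 24:
                resid = np.linalg.norm(X - _reconstruct(A, C)) / max(norm_x, eps)
                if prev - resid < tol:
                    break
                prev = resid
        resid = float(np.linalg.norm(X - _reconstruct(A, C)) / max(norm_x, eps))
        if best is None or resid < best[0]:
            best = (resid, A, C)
    resid, A, C = best

    # unit-norm node columns; the (squared) scale moves into the time factor
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    A = A / scale
    C = C * scale**2
    return FactorModel(r, A, C, dict(tensor.node_index), resid)


def assign_components(model: FactorModel, tn: TemporalNetwork) -> Dict[Event, int]:
    """Label each event with the component of largest reconstruction value
    a_ic * a_jc * g_tc at its (link, time); ties break to the lowest index."""
    labels: Dict[Event, int] = {}
    for e in tn.events:
        a = model.node_factors[model.node_index[e.i]]
        b = model.node_factors[model.node_index[e.j]]
        g = model.time_factors[e.t]
        labels[e] = int(np.argmax(a * b * g))
    return labels


def core_consistency(tensor: ContactTensor, model: FactorModel) -> float:
    """CORCONDIA: 100 * (1 - ||G - I||^2 / r), where G is the least-squares
    Tucker core given the fixed CP factors and I the superdiagonal core.

    100 means the CP structure is appropriate; values fall (possibly below
    zero) when the model over-fits the data.
    """
    A = model.node_factors
    C = model.time_factors
    r = model.rank
    pa = np.linalg.pinv(A)
    pc = np.linalg.pinv(C)
    G = np.einsum("pi,qj,st,ijt->pqs", pa, pa, pc, tensor.array, optimize=True)
    ideal = np.zeros((r, r, r))
    ideal[np.arange(r), np.arange(r), np.arange(r)] = 1.0
    return float(100.0 * (1.0 - ((G - ideal) ** 2).sum() / r))


def select_rank(
    tensor: ContactTensor,
    ranks: Sequence[int] = tuple(range(2, 21)),
    threshold: float = 90.0,
    seed: Optional[int] = None,
    **decompose_kwargs,
) -> Tuple[int, Dict[int, float]]:
    """Largest rank whose core consistency stays above ``threshold``.

    Ranks are scanned in increasing order and scanning stops at the first
    rank that drops below the threshold ("stays above" is read as: every
    rank up to the selected one passes).  If even the smallest rank fails,
    it is returned with a warning.
    """
    ranks = sorted(ranks)
    scores: Dict[int, float] = {}
    selected: Optional[int] = None
    rng = np.random.default_rng(seed)
    for r in ranks:
        model = decompose(tensor, r, seed=int(rng.integers(0, 2**31 - 1)), **decompose_kwargs)
        scores[r] = core_consistency(tensor, model)
        if scores[r] >= threshold:
            selected = r
        else:
            break
    if selected is None:
        warnings.warn("no rank reached the core-consistency threshold", stacklevel=2)
        selected = ranks[0]
    return selected, scores


def write_labels(labels: Dict[Event, int], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(labels):
            fh.write(f"{e.token}\t{labels[e]}\n")
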