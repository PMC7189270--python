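"""Epidemic-size regression from event coordinates.

Predictors per embedded event: its d coordinates, their squares, and the
euclidean distance to the temporally first embedded event — 2d + 1 columns
in all.  An ordinary-least-squares model is scored by 10-fold
cross-validation with the held-out coefficient of determination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold

from eventemb.embedding import EventEmbedding
from eventemb.temporal_io import Event

__all__ = ["FeatureTable", "PredictionReport", "build_features", "fit_and_score"]


@dataclass
class FeatureTable:
    events: List[Event]
    X: np.ndarray  # (n, 2d + 1)
    y: np.ndarray  # (n,)
    dimension: int
    n_excluded: int = 0  # events lacking vectors, dropped

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.events), 2 * self.dimension + 1):
            raise ValueError("feature matrix has wrong shape")
        if len(self.y) != len(self.events):
            raise ValueError("target length mismatch")


@dataclass
class PredictionReport:
    r2_mean: float
    r2_std: float
    per_fold_r2: List[float]
    n_rows: int
    ridge_fallback: bool = False


def build_features(emb: EventEmbedding, sizes: Dict[Event, int]) -> FeatureTable:
    """Assemble the regression table for every embedded event.

    The distance feature is measured to the embedded event with minimal
    (t, i, j); every embedded event must have a simulated size.
    """
    embedded = sorted(e for e in sizes if e in emb)
    if not embedded:
        raise ValueError("no embedded event has a target size")
    missing = [e.token for e in sorted(sizes) if e not in emb]
    first = embedded[0]
    coords = np.stack([emb.vector(e) for e in embedded]).astype(float)
    dist_to_first = np.linalg.norm(coords - emb.vector(first), axis=1)
    X = np.hstack([coords, coords**2, dist_to_first[:, None]])
    y = np.array([sizes[e] for e in embedded], dtype=float)
    return FeatureTable(embedded, X, y, emb.dimension, n_excluded=len(missing))


def fit_and_score(
    table: FeatureTable, folds: int = 10, seed: Optional[int] = None
) -> PredictionReport:
    """OLS under k-fold cross-validation; held-out r² per fold.

    r² = 1 - SS_res / SS_tot on the validation fold (may be negative).
    A singular design triggers a ridge fallback with a logged warning.
    """
    n = len(table.y)
    if n < folds:
        raise ValueError(f"need at least {folds} rows, got {n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores: List[float] = []
    used_ridge = False
    for train_idx, test_idx in kf.split(table.X):
        X_tr, y_tr = table.X[train_idx], table.y[train_idx]
        X_te, y_te = table.X[test_idx], table.y[test_idx]
        model = LinearRegression()
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            try:
                model.fit(X_tr, y_tr)
                if not np.all(np.isfinite(model.coef_)):
                    raise RuntimeWarning("non-finite coefficients")
            except (RuntimeWarning, np.linalg.LinAlgError):
                used_ridge = True
                model = Ridge(alpha=1e-6)
                model.fit(X_tr, y_tr)
        scores.append(float(r2_score(y_te, model.predict(X_te))))
    if used_ridge:
        warnings.warn("singular design: fell back to ridge regression", stacklevel=2)
    return PredictionReport(
        r2_mean=float(np.mean(scores)),
        r2_std=float(np.std(scores)),
        per_fold_r2=scores,
        n_rows=n,
        ridge_fallback=used_ridge,
    )
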