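"""Class-imbalance correction for a binary one-vs-rest training set.

Two complementary resamplers:

* **Neighbourhood cleaning rule (NCL)** — undersampling: a sample is
  removed when at least two of its three nearest neighbours (Euclidean,
  self excluded) carry a different class. Scope is configurable: restrict
  removal to the majority class (the default, NCL's role as a majority
  undersampler), or clean any sample regardless of class.
* **SMOTE** — oversampling: each synthetic minority sample lies on the
  segment joining a minority sample to one of its k nearest minority
  neighbours, s = a + u·(b − a) with u ~ Uniform(0, 1).

``rebalance`` composes them (clean first, then synthesise up to the target
minority/majority ratio) and tags every output row with its provenance so
downstream cross-validation can prove no synthetic row leaks into an
evaluation fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class ResamplingConfig:
    smote_k: int = 5
    ncl_k: int = 3
    target_ratio: float = 1.0
    ncl_scope: str = "majority_only"  # or "any_class"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.ncl_k < 1:
            raise ValueError("ncl_k must be >= 1")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")
        if self.ncl_scope not in ("any_class", "majority_only"):
            raise ValueError(f"unknown ncl_scope {self.ncl_scope!r}")


@dataclass
class ResampledSet:
    """Rebalanced training set with per-row provenance.

    ``provenance`` has one record per output row: origin "original" rows
    carry their source row index; origin "synthetic" rows carry the two
    parent row indices and the interpolation weight u. ``removed_indices``
    lists input rows dropped by NCL.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list[dict] = field(default_factory=list)
    removed_indices: list[int] = field(default_factory=list)

    def provenance_table(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.provenance):
            rows.append(
                {
                    "row_id": i,
                    "origin": rec["origin"],
                    "parent_ids": ";".join(str(p) for p in rec.get("parents", [])),
                    "u": rec.get("u", ""),
                }
            )
        return pd.DataFrame(rows, columns=["row_id", "origin", "parent_ids", "u"])


def _nearest_neighbours(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of each row's k nearest rows (self excluded).

    Distance ties are broken by lowest row index (stable argsort), so the
    neighbour sets are reproducible.
    """
    d2 = cdist(X, X, metric="sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def ncl_undersample(X: np.ndarray, y: np.ndarray, config: ResamplingConfig) -> np.ndarray:
    """Return indices of rows retained after neighbourhood cleaning.

    All neighbourhoods are evaluated on the original data, then flagged
    rows are removed together (no cascade).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if n < config.ncl_k + 1:
        warnings.warn(
            f"too few rows ({n}) for {config.ncl_k}-NN cleaning; input returned unchanged",
            stacklevel=2,
        )
        return np.arange(n)
    neigh = _nearest_neighbours(X, config.ncl_k)
    disagree = (y[neigh] != y[:, None]).sum(axis=1)
    flagged = disagree >= 2
    if config.ncl_scope == "majority_only":
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        majority = max(counts, key=lambda c: (counts[c], c))
        flagged &= y == majority
    return np.flatnonzero(~flagged)


def smote_oversample(
    X_minority: np.ndarray,
    n_synthetic: int,
    config: ResamplingConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Generate synthetic minority rows along neighbour-joining segments.

    Returns the synthetic matrix and, per row, the parent indices (into
    ``X_minority``) and interpolation weight u.
    """
    X_minority = np.asarray(X_minority, dtype=float)
    if n_synthetic < 0:
        raise ValueError("n_synthetic must be >= 0")
    if X_minority.shape[0] < 2:
        raise ValueError("SMOTE needs at least two minority rows to form a segment")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_synthetic == 0:
        return np.empty((0, X_minority.shape[1])), []
    k = min(config.smote_k, X_minority.shape[0] - 1)
    neigh = _nearest_neighbours(X_minority, k)
    anchors = rng.integers(0, X_minority.shape[0], size=n_synthetic)
    partner_slots = rng.integers(0, k, size=n_synthetic)
    u = rng.uniform(0.0, 1.0, size=n_synthetic)
    partners = neigh[anchors, partner_slots]
    a = X_minority[anchors]
    b = X_minority[partners]
    synthetic = a + u[:, None] * (b - a)
    records = [
        {"parents": (int(anchors[i]), int(partners[i])), "u": float(u[i])}
        for i in range(n_synthetic)
    ]
    return synthetic, records


def ncl_clean(X: np.ndarray, y: np.ndarray, config: ResamplingConfig) -> np.ndarray:
    """NCL with a safety rollback: kept row indices, never losing a class.

    If cleaning would annihilate a class entirely, that class's removals
    are rolled back with a warning.
    """
    y = np.asarray(y)
    kept = ncl_undersample(X, y, config)
    kept_mask = np.zeros(len(y), dtype=bool)
    kept_mask[kept] = True
    for c in np.unique(y):
        if not kept_mask[y == c].any():
            warnings.warn(
                f"NCL removed every sample of class {c}; rolling back its removals",
                stacklevel=2,
            )
            kept_mask |= y == c
    return np.flatnonzero(kept_mask)


def rebalance(
    X: np.ndarray, y: np.ndarray, config: ResamplingConfig, apply_ncl: bool = True
) -> ResampledSet:
    """NCL-clean, then SMOTE the minority up to the target ratio.

    If cleaning would annihilate a class, its removals are rolled back
    with a warning. Surviving original rows keep their exact values.
    ``apply_ncl=False`` skips the cleaning step (SMOTE only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"rebalance requires binary labels, got classes {classes.tolist()}")

    kept = ncl_clean(X, y, config) if apply_ncl else np.arange(len(y))
    kept_mask = np.zeros(len(y), dtype=bool)
    kept_mask[kept] = True
    removed = np.flatnonzero(~kept_mask).tolist()

    y_kept = y[kept]
    counts = {int(c): int((y_kept == c).sum()) for c in classes}
    minority = min(counts, key=lambda c: (counts[c], c))
    majority = max(counts, key=lambda c: (counts[c], -c))
    n_needed = int(np.ceil(config.target_ratio * counts[majority])) - counts[minority]

    provenance = [{"origin": "original", "parents": (int(i),)} for i in kept]
    X_out, y_out = X[kept], y_kept
    if n_needed > 0:
        minority_rows = kept[y_kept == minority]
        if len(minority_rows) < 2:
            warnings.warn(
                f"minority class {minority} has {len(minority_rows)} sample(s) after "
                "cleaning; SMOTE skipped",
                stacklevel=2,
            )
        else:
            rng = np.random.default_rng(config.seed)
            synthetic, records = smote_oversample(X[minority_rows], n_needed, config, rng)
            X_out = np.vstack([X_out, synthetic])
            y_out = np.concatenate([y_out, np.full(n_needed, minority, dtype=int)])
            for rec in records:
                a, b = rec["parents"]
                provenance.append(
                    {
                        "origin": "synthetic",
                        "parents": (int(minority_rows[a]), int(minority_rows[b])),
                        "u": rec["u"],
                    }
                )
    return ResampledSet(X=X_out, y=y_out, provenance=provenance, removed_indices=removed)
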