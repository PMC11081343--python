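"""Quantile binarization of episode features and cohort-lattice assignment.

Raw claims-derived count features are sparse and heavy tailed; the design
matrix fed to the regression is therefore all-binary.  Each numeric feature
is expanded into one column per surviving quantile cutoff, coding the
inequality 1{x ≥ cutoff}, with duplicate cutoff values eliminated so every
column is distinct.  Quantiles use the lower (type-1) empirical definition —
exactly reproducible from sorted order, no interpolation.

Separately, the quarterly-history block of the feature vector is projected
to a low-dimensional embedding by a sparse linear factorization; thresholding
each embedding dimension at its training median yields 2^latent_dim history
groups, which crossed with other discrete episode attributes (e.g. diagnostic
category, comorbidity flags) define the cohort lattice on which all model
parameters vary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .decomposition import Lattice

__all__ = ["CutoffTable", "HistoryEmbedding", "DEFAULT_QUANTILE_GRID",
           "compute_cutoffs", "binarize", "embed_history", "assign_cohort",
           "assign_cohorts"]

# deciles plus upper-tail probes for the heavy right tail
DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10)) + (0.95, 0.99)


@dataclass
class CutoffTable:
    """Per-feature deduplicated quantile cutoffs defining the binary design."""

    feature_names: list
    cutoffs: list            # list of 1-d float arrays, one per feature
    quantile_grid: tuple
    dropped: list            # bool per feature (constant / no surviving cutoff)

    def __post_init__(self):
        for name, c in zip(self.feature_names, self.cutoffs):
            c = np.asarray(c, dtype=np.float64)
            if c.size and np.any(np.diff(c) <= 0):
                raise ValueError(f"cutoffs for {name!r} not strictly increasing")

    @property
    def column_names(self) -> list:
        return [f"{name} >= {cut:g}"
                for name, cuts, drop in zip(self.feature_names, self.cutoffs,
                                            self.dropped)
                if not drop for cut in cuts]

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "cutoffs": [np.asarray(c).tolist() for c in self.cutoffs],
            "quantile_grid": list(self.quantile_grid),
            "dropped": [bool(d) for d in self.dropped],
        })

    @classmethod
    def from_json(cls, text: str) -> "CutoffTable":
        d = json.loads(text)
        return cls(d["feature_names"],
                   [np.asarray(c, dtype=np.float64) for c in d["cutoffs"]],
                   tuple(d["quantile_grid"]), d["dropped"])


def compute_cutoffs(feature_matrix, quantile_grid=DEFAULT_QUANTILE_GRID,
                    feature_names=None) -> CutoffTable:
    """Type-1 empirical quantiles per feature, deduplicated and sorted."""
    X = np.asarray(feature_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("feature matrix must be 2-d with at least one row")
    grid = np.asarray(quantile_grid, dtype=np.float64)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1) \
            or np.any(np.diff(grid) <= 0):
        raise ValueError("quantile grid must be strictly increasing within (0, 1)")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    bad = ~np.isfinite(X)
    if bad.any():
        j = int(np.flatnonzero(bad.any(axis=0))[0])
        raise ValueError(f"non-finite values in feature {feature_names[j]!r}")
    cutoffs, dropped = [], []
    for j in range(X.shape[1]):
        col = X[:, j]
        qs = np.quantile(col, grid, method="inverted_cdf")
        cuts = np.unique(qs)
        # a cutoff at or below the minimum yields an all-ones column: constant,
        # carries no contrast, so it is removed like a duplicate
        cuts = cuts[cuts > col.min()]
        cutoffs.append(cuts)
        dropped.append(cuts.size == 0)
    return CutoffTable(list(feature_names), cutoffs, tuple(grid.tolist()), dropped)


def binarize(feature_matrix, table: CutoffTable):
    """Expand features into 1{x ≥ cutoff} columns; returns (matrix, names)."""
    X = np.asarray(feature_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(table.feature_names):
        raise ValueError(f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'}"
                         f" columns, cutoff table describes {len(table.feature_names)}")
    cols = []
    for j, (cuts, drop) in enumerate(zip(table.cutoffs, table.dropped)):
        if drop:
            continue
        cols.append((X[:, j][:, None] >= np.asarray(cuts)[None, :]))
    design = (np.concatenate(cols, axis=1) if cols
              else np.zeros((X.shape[0], 0))).astype(np.float64)
    return design, table.column_names


@dataclass
class HistoryEmbedding:
    """Sparse linear projection of the history block plus bucketization cutoffs."""

    loading: np.ndarray        # (n_history_features, latent_dim)
    cutoffs: np.ndarray        # (latent_dim,) — training medians by default
    latent_dim: int = field(default=5)

    def __post_init__(self):
        self.loading = np.asarray(self.loading, dtype=np.float64)
        self.cutoffs = np.atleast_1d(np.asarray(self.cutoffs, dtype=np.float64))
        if self.latent_dim < 1 or self.loading.shape[1] != self.latent_dim \
                or self.cutoffs.shape != (self.latent_dim,):
            raise ValueError("inconsistent embedding shapes")

    def scores(self, history_matrix) -> np.ndarray:
        H = np.asarray(history_matrix, dtype=np.float64)
        return H @ self.loading

    @property
    def n_groups(self) -> int:
        return 2 ** self.latent_dim

    def to_json(self) -> str:
        return json.dumps({"loading": self.loading.tolist(),
                           "cutoffs": self.cutoffs.tolist(),
                           "latent_dim": self.latent_dim})

    @classmethod
    def from_json(cls, text: str) -> "HistoryEmbedding":
        d = json.loads(text)
        return cls(np.asarray(d["loading"], dtype=np.float64),
                   np.asarray(d["cutoffs"], dtype=np.float64), d["latent_dim"])


def embed_history(history_matrix, latent_dim=5, sparsity_weight=0.1,
                  seed=0) -> HistoryEmbedding:
    """Fit a sparse nonnegative linear factorization of the history counts.

    H ≈ S·W with an L1 penalty on the factors; the stored loading matrix is
    the pseudo-inverse of W so new episodes project linearly and
    deterministically.  Bucketization cutoffs are the training medians of the
    projected scores.
    """
    H = np.asarray(history_matrix, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("history matrix must be 2-d and nonempty")
    if np.any(H < 0):
        raise ValueError("history counts must be nonnegative")
    if latent_dim >= H.shape[1]:
        raise ValueError(f"latent_dim {latent_dim} must be < feature count "
                         f"{H.shape[1]}")
    if not H.any():
        loading = np.zeros((H.shape[1], latent_dim))
        return HistoryEmbedding(loading, np.zeros(latent_dim), latent_dim)
    from sklearn.decomposition import NMF
    nmf = NMF(n_components=latent_dim, init="nndsvda", max_iter=5000,
              alpha_W=sparsity_weight / H.shape[0], alpha_H="same",
              l1_ratio=1.0, random_state=int(seed), tol=1e-6)
    nmf.fit(H)
    loading = np.linalg.pinv(nmf.components_)       # (p_hist, latent_dim)
    scores = H @ loading
    # order dimensions by explained variance so dimension 0 is dominant
    order = np.argsort(-scores.var(axis=0), kind="stable")
    loading = loading[:, order]
    cutoffs = np.median(H @ loading, axis=0)
    return HistoryEmbedding(loading, cutoffs, latent_dim)


def history_group(scores, embedding: HistoryEmbedding):
    """Bits 1{score_d ≥ median_d}; dimension 0 is the least significant bit."""
    scores = np.asarray(scores, dtype=np.float64)
    bits = (scores >= embedding.cutoffs).astype(int)
    weights = 2 ** np.arange(embedding.latent_dim)
    return bits @ weights


def assign_cohort(scores, embedding: HistoryEmbedding, discrete_attrs,
                  lattice: Lattice):
    """Cohort multi-index κ = (history_group, attr_1, …) for one episode."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (embedding.latent_dim,):
        raise ValueError("score vector length must equal latent_dim")
    attrs = [int(a) for a in np.atleast_1d(discrete_attrs)] if discrete_attrs \
        is not None and np.size(discrete_attrs) else []
    kappa = (int(history_group(scores, embedding)), *attrs)
    if len(kappa) != lattice.ndim:
        raise ValueError(f"κ has {len(kappa)} dims, lattice has {lattice.ndim}")
    for k, s, name in zip(kappa, lattice.sizes, lattice.names):
        if not 0 <= k < s:
            raise ValueError(f"attribute {name!r} value {k} outside 0..{s - 1}")
    return kappa


def assign_cohorts(score_matrix, embedding: HistoryEmbedding, attr_matrix,
                   lattice: Lattice) -> np.ndarray:
    """Vectorized cohort assignment: (n, D) multi-index array."""
    groups = history_group(np.asarray(score_matrix, dtype=np.float64), embedding)
    cols = [np.asarray(groups).reshape(-1)]
    if attr_matrix is not None and np.size(attr_matrix):
        A = np.asarray(attr_matrix, dtype=int)
        cols.extend(A[:, j] for j in range(A.shape[1]))
    kappas = np.stack(cols, axis=1)
    for d, s in enumerate(lattice.sizes):
        if np.any((kappas[:, d] < 0) | (kappas[:, d] >= s)):
            raise ValueError(f"cohort dimension {lattice.names[d]!r} out of range")
    return kappas
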