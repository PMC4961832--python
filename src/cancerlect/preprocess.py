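"""Class balancing (SMOTE) and feature ranking/selection (MRMD).

SMOTE appends synthetic minority rows: each new row interpolates between a
minority sample and one of its k nearest minority neighbors,
``x_new = x + u (x_nn - x)`` with u ~ U[0, 1]. At the default rate of 100 %
it doubles the minority class, turning a 178-positive / 226-negative
training set into 356 / 226 = 582 rows. Balancing is meant for training
folds only; evaluation folds and supplied test sets stay untouched.

MRMD ranks features by the sum of a relevance term (absolute Pearson
correlation of the column with the 0/1 label) and a distance term (mean
distance of the min-max-scaled column to every other scaled column,
normalized by the largest such mean so both terms live in [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .dataset import FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    """rate: synthetic rows as a percentage of the minority class;
    k_neighbors: neighborhood size; seed: generator seed."""

    rate: float = 100.0
    k_neighbors: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote(table: FeatureTable, config: SmoteConfig = SmoteConfig()) -> FeatureTable:
    """Oversample the minority class of a labelled table.

    Original rows are preserved verbatim and first; ``floor(rate/100 *
    n_minority)`` synthetic minority rows are appended. Parents cycle
    through the minority rows (the original algorithm's convention), the
    neighbor and interpolation coefficient come from the seeded generator.
    Neighbor search is Euclidean on the raw feature values; pre-scale the
    table if features live on very different scales.
    """
    if table.labels is None:
        raise ValueError("SMOTE needs a labelled table")
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() == 0:
        raise ValueError("SMOTE needs both classes present")
    if config.rate == 0:
        return table
    minority = int(np.argmin(counts))
    n_min = int(counts[minority])
    if n_min <= config.k_neighbors:
        raise ValueError(
            f"minority class has {n_min} rows, needs > k_neighbors={config.k_neighbors}; "
            "use a smaller k"
        )
    n_new = math.floor(config.rate / 100.0 * n_min)
    if n_new == 0:
        return table
    X_min = table.X[table.labels == minority]
    nn = NearestNeighbors(n_neighbors=config.k_neighbors + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(config.seed)
    synth = np.empty((n_new, table.d))
    for t in range(n_new):
        i = t % n_min
        j = int(rng.integers(config.k_neighbors))
        u = rng.uniform()
        synth[t] = X_min[i] + u * (X_min[neigh[i, j]] - X_min[i])
    X_out = np.vstack([table.X, synth])
    labels_out = np.concatenate([table.labels, np.full(n_new, minority, dtype=int)])
    return FeatureTable(table.feature_names, X_out, labels_out, list(table.provenance))


# ---------------------------------------------------------------------------
# MRMD

DISTANCE_METRICS = ("euclidean", "cosine", "tanimoto")


@dataclass
class MrmdRanking:
    feature_names: list[str]
    relevance: np.ndarray
    distance: np.ndarray
    combined: np.ndarray
    rank: np.ndarray  # 1 = best
    metric: str = "euclidean"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "relevance": self.relevance,
                "distance": self.distance,
                "combined": self.combined,
                "rank": self.rank,
            }
        )

    def top(self, m: int) -> list[int]:
        """Column indices of the m best-ranked features, original order."""
        return sorted(np.flatnonzero(self.rank <= m))


def _pairwise_distance(Xs: np.ndarray, metric: str) -> np.ndarray:
    """d x d distance matrix between scaled feature columns."""
    cols = Xs.T
    if metric == "euclidean":
        return squareform(pdist(cols, "euclidean"))
    if metric == "cosine":
        D = squareform(pdist(cols, "cosine"))
        return np.nan_to_num(D, nan=0.0)  # zero columns have undefined angle
    if metric == "tanimoto":
        dot = cols @ cols.T
        sq = np.diag(dot)
        denom = sq[:, None] + sq[None, :] - dot
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, dot / denom, 1.0)
        return 1.0 - sim
    raise ValueError(f"unknown distance metric {metric!r}; choose from {DISTANCE_METRICS}")


def mrmd_rank(table: FeatureTable, metric: str = "euclidean") -> MrmdRanking:
    """Rank features by relevance-to-label plus mean distance to other features.

    Constant columns get relevance 0; distance means are normalized by the
    maximum so scores lie in [0, 1]; ranks break ties by original column
    order. A single-feature table yields a relevance-only ranking (logged).
    """
    if table.labels is None:
        raise ValueError("MRMD needs a labelled table")
    if table.n < 2 or len(np.unique(table.labels)) < 2:
        raise ValueError("MRMD needs >= 2 rows with both classes present")
    y = table.labels.astype(float)
    yc = y - y.mean()
    Xc = table.X - table.X.mean(axis=0)
    col_sd = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(Xc.T @ yc) / (col_sd * np.sqrt((yc**2).sum()))
    rel = np.nan_to_num(rel, nan=0.0)

    span = table.X.max(axis=0) - table.X.min(axis=0)
    Xs = np.where(span > 0, (table.X - table.X.min(axis=0)) / np.where(span > 0, span, 1.0), 0.0)
    if table.d == 1:
        logger.warning("single feature: MRMD distance term is 0")
        dist = np.zeros(1)
    else:
        D = _pairwise_distance(Xs, metric)
        dist = D.sum(axis=1) / (table.d - 1)
        if dist.max() > 0:
            dist = dist / dist.max()
    combined = rel + dist
    # stable sort: descending combined, ties by original column order
    order = np.lexsort((np.arange(table.d), -combined))
    rank = np.empty(table.d, dtype=int)
    rank[order] = np.arange(1, table.d + 1)
    return MrmdRanking(list(table.feature_names), rel, dist, combined, rank, metric)


def mrmd_select(
    table: FeatureTable,
    ranking: MrmdRanking,
    m: int | str = "auto",
    cv_folds: int = 10,
    trees: int = 100,
    seed: int = 1,
) -> FeatureTable:
    """Keep the top-m ranked features, preserving original column order.

    ``m="auto"`` sweeps every rank-prefix m = 1..d, scores each by
    ``cv_folds``-fold cross-validated random-forest accuracy, and keeps the
    best (smallest m on ties). The sweep cost is d model fits per fold, so
    reserve auto mode for already-small tables.
    """
    if m == "auto":
        from .classify import cross_validate, rf_learner

        best_m, best_acc = 1, -1.0
        for cand in range(1, table.d + 1):
            sub = _subset(table, ranking.top(cand))
            report = cross_validate(sub, rf_learner(trees=trees, seed=seed), k=cv_folds, seed=seed)
            if report.accuracy > best_acc + 1e-12:
                best_m, best_acc = cand, report.accuracy
        logger.info("mrmd auto selection: m=%d (CV accuracy %.4f)", best_m, best_acc)
        m = best_m
    if not 1 <= int(m) <= table.d:
        raise ValueError(f"m must be in [1, {table.d}], got {m}")
    return _subset(table, ranking.top(int(m)))


def _subset(table: FeatureTable, cols: list[int]) -> FeatureTable:
    return FeatureTable(
        [table.feature_names[c] for c in cols],
        table.X[:, cols],
        table.labels,
        list(table.provenance),
    )
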