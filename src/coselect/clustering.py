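"""Response-profile scaling and hierarchical clustering.

GI profiles are made comparable across compounds of different potency
by median-centering each drug's column and normalizing it to unit sum
of squares (the Cluster-3.0 convention). Drugs (or cell lines) are then
clustered by average linkage over the Pearson-correlation distance
d = 1 - r, computed pairwise-complete so untested drug/line
combinations need no imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Minimum pairwise-complete positions for a defined correlation.
MIN_COMPLETE = 3


@dataclass
class ScaledResponseMatrix:
    """Cell-line x drug matrix of scaled growth-inhibition scores."""

    data: pd.DataFrame
    constant_columns: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.data.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.data.columns)


def scale_profiles(gi_matrix: pd.DataFrame, min_values: int = MIN_COMPLETE) -> ScaledResponseMatrix:
    """Median-center then normalize each drug's GI column.

    After scaling, non-missing entries of each column have median 0 and
    sum of squares 1. Missing entries stay missing. Constant columns are
    centered to zero and flagged (normalization would divide by zero);
    all-missing or too-sparse columns are dropped with a log entry.
    Column (not row) operations only: potency varies by compound.
    """
    scaled = {}
    constant, dropped = [], []
    for drug in gi_matrix.columns:
        col = gi_matrix[drug].astype(float)
        values = col.dropna()
        if len(values) < min_values:
            dropped.append(drug)
            logger.warning("dropping column %r: %d non-missing values", drug, len(values))
            continue
        centered = col - values.median()
        ss = float((centered.dropna() ** 2).sum())
        if ss == 0.0:
            constant.append(drug)
            scaled[drug] = centered
        else:
            scaled[drug] = centered / np.sqrt(ss)
    frame = pd.DataFrame(scaled, index=gi_matrix.index)
    return ScaledResponseMatrix(frame, constant, dropped)


def pearson_correlation(u, v) -> tuple[float, int]:
    """Pairwise-complete Pearson r and the number of complete positions."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = ~(np.isnan(u) | np.isnan(v))
    n = int(ok.sum())
    if n < MIN_COMPLETE:
        return float("nan"), n
    uu, vv = u[ok] - u[ok].mean(), v[ok] - v[ok].mean()
    denom = np.sqrt((uu**2).sum() * (vv**2).sum())
    if denom == 0:
        return float("nan"), n
    return float((uu * vv).sum() / denom), n


def pearson_distance(u, v) -> float:
    """Correlation distance d = 1 - r in [0, 2] on pairwise-complete
    positions; undefined (NaN, with a warning) below 3 complete pairs."""
    r, n = pearson_correlation(u, v)
    if np.isnan(r):
        logger.warning("undefined correlation (%d complete positions)", n)
        return float("nan")
    return 1.0 - r


@dataclass
class ClusterTree:
    """Average-linkage merge history over Pearson distances."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix over `labels`
    excluded: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = [self.labels[i] for i in leaves_list(self.merges)]
        return order + list(self.excluded)

    @property
    def n_leaves(self) -> int:
        return len(self.labels) + len(self.excluded)


def hierarchical_cluster(matrix: ScaledResponseMatrix | pd.DataFrame,
                         axis: str = "drugs") -> ClusterTree:
    """UPGMA (average-linkage) tree over the Pearson distance matrix.

    ``axis='drugs'`` clusters compounds (columns), ``'cell_lines'``
    clusters the panel (rows). Entities are ordered lexicographically
    before linkage so ties break deterministically. Entities with any
    undefined pairwise distance are appended as singletons and logged.
    """
    frame = matrix.data if isinstance(matrix, ScaledResponseMatrix) else matrix
    if axis == "drugs":
        profiles = {c: frame[c].to_numpy(dtype=float) for c in frame.columns}
    elif axis == "cell_lines":
        profiles = {r: frame.loc[r].to_numpy(dtype=float) for r in frame.index}
    else:
        raise ValueError("axis must be 'drugs' or 'cell_lines'")
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("need at least two entities to cluster")
    m = len(names)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dist[i, j] = dist[j, i] = pearson_distance(profiles[names[i]], profiles[names[j]])
    defined = ~np.isnan(dist).any(axis=1)
    excluded = [n for n, ok in zip(names, defined) if not ok]
    if excluded:
        logger.warning("excluding entities with undefined distances: %s", excluded)
    kept = [n for n, ok in zip(names, defined) if ok]
    if len(kept) < 2:
        raise ValueError("fewer than two entities with defined pairwise distances")
    idx = [names.index(n) for n in kept]
    merges = linkage(squareform(dist[np.ix_(idx, idx)], checks=False), method="average")
    return ClusterTree(kept, merges, excluded)


def subcluster_correlation(matrix: ScaledResponseMatrix | pd.DataFrame, members) -> tuple[float, int]:
    """Mean pairwise Pearson r over a drug set (pairwise-complete).

    Returns ``(mean_r, n_pairs)``; pairs with undefined correlation are
    dropped and reflected in the reduced pair count.
    """
    frame = matrix.data if isinstance(matrix, ScaledResponseMatrix) else matrix
    members = sorted(members)
    if len(members) < 2:
        raise ValueError("a subcluster needs at least two members")
    rs = []
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            r, _ = pearson_correlation(
                frame[members[i]].to_numpy(dtype=float),
                frame[members[j]].to_numpy(dtype=float),
            )
            if not np.isnan(r):
                rs.append(r)
    if not rs:
        return float("nan"), 0
    return float(np.mean(rs)), len(rs)
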