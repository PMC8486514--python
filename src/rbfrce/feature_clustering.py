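"""Correlation-distance clustering of features into feature classes.

Features (viewed as vectors across samples) are grouped by the correlation
distance D_ij = 1 - r_ij, with r_ij the Pearson correlation over samples.
K-means under this distance is realised by standardizing each feature vector
to zero mean and unit sample SD and running ordinary Euclidean K-means:
for standardized u, v,

    ||u - v||^2 = 2 (n - 1) (1 - r),

so squared Euclidean distance is an exact monotone transform of the
correlation distance and the standard assignment/update steps apply
unchanged.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .bit_ensemble import _norm_seed
from .data_io import LabeledMatrix


@dataclasses.dataclass
class FeatureCluster:
    """A feature class: member feature ids plus an importance-based score."""

    cluster_index: int
    member_ids: frozenset
    score: float | None = None


@dataclasses.dataclass(frozen=True)
class ClusteringConfig:
    """K-means settings; n_clusters=None means ceil(sqrt(p)) at call time."""

    n_clusters: int | None = None
    max_iterations: int = 300
    seed: int = 0


def correlation_distance(f_i: np.ndarray, f_j: np.ndarray) -> float:
    """1 - Pearson correlation of two feature vectors across samples.

    Ranges over [0, 2]: 0 for perfectly correlated, 2 for perfectly
    anti-correlated. A constant vector has undefined correlation; it is
    treated as uncorrelated (distance 1) with a warning, so uninformative
    features are cluster-neutral rather than fatal.
    """
    u = np.asarray(f_i, dtype=float)
    v = np.asarray(f_j, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors, length >= 2")
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        warnings.warn(
            "constant feature vector: correlation undefined, distance set to 1",
            stacklevel=2,
        )
        return 1.0
    r = float(np.dot(u - u.mean(), v - v.mean()) / (u.size * su * sv))
    return 1.0 - r


def standardize_features(
    data: LabeledMatrix, feature_ids: Sequence[str]
) -> np.ndarray:
    """Per-feature vectors standardized across samples (mean 0, sample SD 1).

    Returns shape (n_features, n_samples). Constant features map to the zero
    vector (equidistant from everything, matching distance-1 convention up
    to centering).
    """
    sub = data.subset_features(list(feature_ids))
    V = sub.values.T.astype(float)  # features x samples
    mean = V.mean(axis=1, keepdims=True)
    sd = V.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(V)
    ok = sd[:, 0] > 0
    out[ok] = (V[ok] - mean[ok]) / sd[ok]
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} constant feature(s) mapped to the zero vector",
            stacklevel=2,
        )
    return out


def default_n_clusters(n_features: int) -> int:
    return math.ceil(math.sqrt(n_features))


def cluster_features(
    data: LabeledMatrix,
    config: ClusteringConfig,
    active_features: Sequence[str] | None = None,
) -> list[FeatureCluster]:
    """Partition the active features into correlation-distance clusters.

    Runs k-means++-seeded Euclidean K-means on standardized feature vectors
    (equivalent in ordering to correlation distance; see module docstring).
    The returned clusters always partition the active feature set; empty
    clusters cannot occur (K-means reassigns the farthest points into them).
    Deterministic given ``config.seed``.
    """
    if active_features is None:
        active_features = list(data.feature_ids)
    else:
        active_features = list(active_features)
    p = len(active_features)
    k = config.n_clusters if config.n_clusters is not None else default_n_clusters(p)
    if k < 1 or k > p:
        raise ValueError(f"n_clusters={k} must lie in [1, {p}] for {p} active features")

    V = standardize_features(data, active_features)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=1,
        max_iter=config.max_iterations,
        random_state=_norm_seed(config.seed),
    )
    assign = km.fit_predict(V)

    clusters = []
    for c in range(k):
        members = frozenset(
            active_features[i] for i in np.flatnonzero(assign == c)
        )
        if members:
            clusters.append(FeatureCluster(cluster_index=c, member_ids=members))
    assigned = set().union(*(cl.member_ids for cl in clusters))
    assert assigned == set(active_features), "clusters must partition features"
    return clusters
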