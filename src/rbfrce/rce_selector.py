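"""Recursive cluster elimination driven by OOB permutation importance.

The selection loop alternates two phases:

1. *Cluster elimination* — fit the ensemble on the active features, compute
   each feature's permutation importance (fip), score every feature class by
   its best member, Score(S_i) = max_{j in S_i} fip_j, and delete the
   lowest-scoring fraction of clusters wholesale. Scoring a cluster by its
   maximum protects correlated groups that contain even one strong feature,
   while whole groups of irrelevant features disappear in one step.
2. *Feature elimination* — once fewer clusters remain than the switch
   threshold, deletion moves inside the clusters: active features are ranked
   by fip and the lowest fraction is dropped per round.

The loop never deletes past ``target_features`` (the last batch is trimmed,
lowest scores first) and records every deletion, so the final output is a
full ranking of all original features: survivors ordered by their final-fit
fip, then eliminated features in reverse deletion order (later-deleted =
more important). Ties break lexicographically on feature id throughout, and
the whole procedure is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal, Mapping

import numpy as np

from .bit_ensemble import EnsembleConfig, _rng, fit_ensemble
from .data_io import LabeledMatrix, RankingRecord
from .feature_clustering import (
    ClusteringConfig,
    FeatureCluster,
    cluster_features,
    default_n_clusters,
)
from .oob_importance import importance_scores


@dataclasses.dataclass(frozen=True)
class RCEConfig:
    """Settings of the recursive elimination loop.

    drop_fraction / feature_drop_fraction of 0.1 delete 10% of clusters
    (resp. features) per round, giving roughly logarithmic shrinkage;
    switch_threshold=30 moves deletion inside clusters once fewer than 30
    feature classes remain. By default the feature partition is computed once
    and carried through (deleted members removed); set
    ``recluster_each_round`` to re-run K-means on the survivors each round.
    """

    target_features: int = 50
    drop_fraction: float = 0.1
    switch_threshold: int = 30
    feature_drop_fraction: float = 0.1
    recluster_each_round: bool = False
    clustering: ClusteringConfig = dataclasses.field(default_factory=ClusteringConfig)
    ensemble: EnsembleConfig = dataclasses.field(default_factory=EnsembleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_features < 1:
            raise ValueError("target_features must be >= 1")
        for name in ("drop_fraction", "feature_drop_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.switch_threshold < 1:
            raise ValueError("switch_threshold must be >= 1")


@dataclasses.dataclass
class EliminationEntry:
    iteration: int
    phase: str
    deleted_ids: list[str]
    scores_at_deletion: dict[str, float]  # fip of each deleted feature


@dataclasses.dataclass
class SelectionState:
    iteration: int
    active_features: list[str]  # original column order preserved
    clusters: list[FeatureCluster]
    phase: Literal["cluster_elimination", "feature_elimination"]
    elimination_log: list[EliminationEntry]
    final_fips: dict[str, float] | None = None  # filled at termination


def score_cluster(cluster: FeatureCluster, importances: Mapping[str, float]) -> float:
    """Score(S_i) = max over members of fip."""
    if not cluster.member_ids:
        raise ValueError("cannot score an empty cluster")
    missing = [f for f in cluster.member_ids if f not in importances]
    if missing:
        raise ValueError(f"members without importance values: {sorted(missing)[:5]}")
    return max(importances[f] for f in cluster.member_ids)


def _fit_and_score(
    data: LabeledMatrix, active: list[str], config: RCEConfig, round_seed: int
) -> dict[str, float]:
    sub = data.subset_features(active)
    ens_cfg = dataclasses.replace(config.ensemble, seed=round_seed)
    ens = fit_ensemble(sub, ens_cfg)
    imps = importance_scores(ens, sub, seed=round_seed)
    return {imp.feature_id: imp.fip for imp in imps}


def _restrict_clusters(
    clusters: list[FeatureCluster], active: set[str]
) -> list[FeatureCluster]:
    out = []
    for cl in clusters:
        members = cl.member_ids & active
        if members:
            out.append(FeatureCluster(cl.cluster_index, frozenset(members)))
    return out


def _round_seed(config: RCEConfig, iteration: int) -> int:
    return int(_rng(config.seed, 10, iteration).integers(2**31))


def initial_state(data: LabeledMatrix, config: RCEConfig) -> SelectionState:
    """Cluster the full feature set and choose the starting phase."""
    active = [str(f) for f in data.feature_ids]
    k = config.clustering.n_clusters or default_n_clusters(len(active))
    k = min(k, len(active))
    clusters = cluster_features(
        data,
        dataclasses.replace(config.clustering, n_clusters=k),
        active,
    )
    phase = (
        "cluster_elimination" if len(clusters) >= config.switch_threshold
        else "feature_elimination"
    )
    return SelectionState(0, active, clusters, phase, [])


def eliminate_round(
    state: SelectionState, data: LabeledMatrix, config: RCEConfig
) -> SelectionState:
    """One elimination round: fit, score, delete, maybe switch phase."""
    active = list(state.active_features)
    if len(active) <= config.target_features:
        warnings.warn("already at or below target_features; no-op", stacklevel=2)
        return state

    round_seed = _round_seed(config, state.iteration)
    fips = _fit_and_score(data, active, config, round_seed)
    budget = len(active) - config.target_features  # max deletable this round

    deleted: list[str] = []
    if state.phase == "cluster_elimination":
        clusters = _restrict_clusters(state.clusters, set(active))
        scored = sorted(
            clusters,
            key=lambda cl: (score_cluster(cl, fips), min(cl.member_ids)),
        )
        n_del = math.ceil(config.drop_fraction * len(scored))
        for cl in scored[:n_del]:
            members = sorted(cl.member_ids, key=lambda f: (fips[f], f))
            if len(deleted) + len(members) <= budget:
                deleted.extend(members)
            else:  # trim the last batch: drop only the worst members
                deleted.extend(members[: budget - len(deleted)])
                break
    else:
        ranked = sorted(active, key=lambda f: (fips[f], f))  # worst first
        n_del = min(math.ceil(config.feature_drop_fraction * len(active)), budget)
        deleted = ranked[:n_del]

    deleted_set = set(deleted)
    new_active = [f for f in active if f not in deleted_set]
    assert len(new_active) >= config.target_features

    if config.recluster_each_round and len(new_active) > config.target_features:
        k = config.clustering.n_clusters or default_n_clusters(len(new_active))
        k = min(k, len(new_active))
        new_clusters = cluster_features(
            data,
            dataclasses.replace(
                config.clustering,
                n_clusters=k,
                seed=_round_seed(config, state.iteration) ^ 0x5BF5,
            ),
            new_active,
        )
    else:
        new_clusters = _restrict_clusters(state.clusters, set(new_active))

    phase = state.phase
    if phase == "cluster_elimination" and len(new_clusters) < config.switch_threshold:
        phase = "feature_elimination"

    entry = EliminationEntry(
        iteration=state.iteration,
        phase=state.phase,
        deleted_ids=deleted,
        scores_at_deletion={f: fips[f] for f in deleted},
    )
    return SelectionState(
        iteration=state.iteration + 1,
        active_features=new_active,
        clusters=new_clusters,
        phase=phase,
        elimination_log=state.elimination_log + [entry],
    )


def run_rbf_rce(
    data: LabeledMatrix, config: RCEConfig
) -> tuple[list[RankingRecord], SelectionState]:
    """Run the full elimination loop and return a complete feature ranking.

    The ranking covers every original feature: survivors first (by final-fit
    fip, descending), then eliminated features in reverse deletion order,
    within one deletion batch by their fip at deletion (descending). The
    top ``config.target_features`` entries are the selected subset.
    """
    if data.n_classes() < 2:
        raise ValueError("need >=2 classes")

    if data.n_features <= config.target_features:
        state = SelectionState(
            0, [str(f) for f in data.feature_ids], [], "feature_elimination", []
        )
    else:
        state = initial_state(data, config)
        while len(state.active_features) > config.target_features:
            state = eliminate_round(state, data, config)

    final_fips = _fit_and_score(
        data, state.active_features, config, _round_seed(config, state.iteration)
    )
    state.final_fips = final_fips

    ordered = sorted(
        state.active_features, key=lambda f: (-final_fips[f], f)
    )
    records = [
        RankingRecord(feature_id=f, rank=i + 1, score=final_fips[f])
        for i, f in enumerate(ordered)
    ]
    rank = len(records)
    for entry in reversed(state.elimination_log):
        batch = sorted(
            entry.deleted_ids,
            key=lambda f: (-entry.scores_at_deletion[f], f),
        )
        for f in batch:
            rank += 1
            records.append(
                RankingRecord(feature_id=f, rank=rank, score=entry.scores_at_deletion[f])
            )
    assert {r.feature_id for r in records} == set(map(str, data.feature_ids))
    return records, state
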