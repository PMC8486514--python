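"""Out-of-bag permutation importance.

For each tree i and feature f, the feature's values are randomly permuted
among the tree's own OOB samples and the tree's OOB accuracy is recomputed;
the drop

    E_i^f = C_i - C_i^f

is averaged over trees (E^f), its sample variance S^2 uses the m-1
denominator, and the importance is the standardized mean drop

    fip = E^f / S     (fip = 0 when S = 0: no measured influence).

Permuting within the OOB set preserves the feature's marginal distribution
while destroying its association with the labels — the classic permutation
importance, computed per tree on that tree's private validation set.

Each (tree, feature) pair gets one fresh permutation, seeded from
(seed, tree index, feature index), so results are reproducible and invariant
to the order features are requested in. For a random-bits ensemble the
permuted raw feature only changes the selected bits that read it, which is
how the implementation avoids re-evaluating untouched bits; a feature that
no selected bit reads (or, for a plain forest, that the tree never splits
on) has C_i^f = C_i exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .bit_ensemble import FittedEnsemble
from .data_io import LabeledMatrix


@dataclasses.dataclass
class FeatureImportance:
    """Permutation-importance record of one feature."""

    feature_id: str
    per_tree_delta: np.ndarray  # E_i^f over usable trees
    mean_delta: float  # E^f
    variance: float  # S^2, m-1 denominator
    fip: float  # E^f / S, 0 when S == 0


def summarize_deltas(feature_id: str, per_tree_delta: np.ndarray) -> FeatureImportance:
    """Fold per-tree accuracy drops into a FeatureImportance record."""
    d = np.asarray(per_tree_delta, dtype=float)
    mean = float(d.mean()) if d.size else 0.0
    var = float(d.var(ddof=1)) if d.size >= 2 else 0.0
    fip = mean / np.sqrt(var) if var > 0 else 0.0
    return FeatureImportance(feature_id, d, mean, var, float(fip))


def _canonical(ensemble: FittedEnsemble, data: LabeledMatrix):
    order = ensemble.sample_order
    X = data.values[order]
    class_index = {c: i for i, c in enumerate(ensemble.classes)}
    y = np.fromiter(
        (class_index[lab] for lab in data.labels[order]), dtype=np.int64,
        count=len(order),
    )
    return X, y


def _feature_columns(data: LabeledMatrix, features: Sequence[str]) -> np.ndarray:
    pos = {f: i for i, f in enumerate(data.feature_ids)}
    cols = np.empty(len(features), dtype=np.int64)
    for i, f in enumerate(features):
        if f not in pos:
            raise KeyError(f"unknown feature id {f!r}")
        cols[i] = pos[f]
    return cols


_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def _oob_permutation(seed: int, tree_index: int, col: int, rep: int, n: int) -> np.ndarray:
    """Deterministic permutation of range(n) keyed on (seed, tree, feature, rep).

    Counter-based (splitmix64 hash + argsort), so no generator object is
    constructed per call; one fresh independent permutation per key.
    """
    with np.errstate(over="ignore"):
        key = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
        for part in (tree_index, col, rep):
            key = _splitmix64(key + _SM_GAMMA * np.uint64(part + 1))
        vals = _splitmix64(key + _SM_GAMMA * np.arange(1, n + 1, dtype=np.uint64))
    return np.argsort(vals, kind="stable")


def _tree_permuted_deltas(
    ensemble: FittedEnsemble,
    X: np.ndarray,
    y: np.ndarray,
    tree_pos: int,
    cols: np.ndarray,
    seed: int,
    rep: int,
) -> np.ndarray:
    """E_i^f for one tree across the requested feature columns.

    Only features the tree's decision function can see (via a selected bit
    the tree splits on, or a split feature for plain forests) are
    re-evaluated; for every other feature the permuted accuracy equals C_i
    exactly. All re-evaluations for one tree go through a single stacked
    predict call.
    """
    tree, rec = ensemble.trees[tree_pos]
    deltas = np.zeros(len(cols))
    if not rec.has_oob:
        return deltas
    oob = rec.oob
    n_oob = oob.size
    y_oob = y[oob]
    base_acc = rec.oob_accuracy

    split_feats = np.unique(tree.tree_.feature)
    split_feats = split_feats[split_feats >= 0]

    blocks, owners = [], []
    if ensemble.bit_layer is not None:
        layer = ensemble.bit_layer
        sel = ensemble.selected_bits[tree_pos]
        fidx = layer.feature_idx[sel]  # (n_sel, 3)
        wsel = layer.weights[sel]
        # raw features feeding a bit this tree actually splits on
        relevant = set(fidx[split_feats].ravel().tolist()) - {-1}
        todo = [(j, int(c)) for j, c in enumerate(cols) if int(c) in relevant]
        if not todo:
            return deltas
        thr = layer.thresholds[sel]
        scores = layer.linear_scores(X[oob], sel)  # (n_oob, n_sel)
        base_bits = (scores > thr).astype(np.float64)
        for j, c in todo:
            hit_bits, hit_slots = np.nonzero(fidx == c)
            perm = _oob_permutation(seed, rec.tree_index, c, rep, n_oob)
            dx = X[oob][perm, c] - X[oob, c]  # (n_oob,)
            new_bits = base_bits.copy()
            w = wsel[hit_bits, hit_slots]  # weight of c in each hit bit
            new_scores = scores[:, hit_bits] + np.outer(dx, w)
            new_bits[:, hit_bits] = (new_scores > thr[hit_bits]).astype(np.float64)
            blocks.append(new_bits)
            owners.append(j)
    else:
        used = set(split_feats.tolist())
        X_oob = X[oob]
        for j, c in enumerate(cols):
            if int(c) not in used:
                continue  # tree never splits on it: delta 0
            perm = _oob_permutation(seed, rec.tree_index, int(c), rep, n_oob)
            Xp = X_oob.copy()
            Xp[:, c] = X_oob[perm, c]
            blocks.append(Xp)
            owners.append(j)
    if blocks:
        pred = tree.predict(np.vstack(blocks)).reshape(len(blocks), n_oob)
        accs = (pred == y_oob).mean(axis=1)
        for j, acc in zip(owners, accs):
            deltas[j] = base_acc - acc
    return deltas


def permuted_tree_accuracy(
    ensemble: FittedEnsemble,
    data: LabeledMatrix,
    feature: str,
    tree_index: int,
    seed: int = 0,
) -> float:
    """C_i^f: one tree's OOB accuracy after permuting ``feature`` in its OOB set."""
    cols = _feature_columns(data, [feature])
    tree_pos = next(
        (k for k, (_t, rec) in enumerate(ensemble.trees) if rec.tree_index == tree_index),
        None,
    )
    if tree_pos is None:
        raise ValueError(f"no tree with index {tree_index}")
    _tree, rec = ensemble.trees[tree_pos]
    if not rec.has_oob:
        raise ValueError(f"tree {tree_index} has an empty OOB set")
    X, y = _canonical(ensemble, data)
    delta = _tree_permuted_deltas(ensemble, X, y, tree_pos, cols, seed, rep=0)[0]
    return float(rec.oob_accuracy - delta)


def importance_scores(
    ensemble: FittedEnsemble,
    data: LabeledMatrix,
    features: Sequence[str] | None = None,
    seed: int = 0,
    n_permutations: int = 1,
) -> list[FeatureImportance]:
    """Permutation importance of the requested features (default: all).

    Trees with an empty OOB set are excluded; the per-tree delta vectors of
    every feature cover the same usable trees, in tree order. With
    ``n_permutations > 1`` the per-tree delta is averaged over that many
    independent permutations.
    """
    if features is None:
        features = list(data.feature_ids)
    cols = _feature_columns(data, features)
    usable = [k for k, (_t, rec) in enumerate(ensemble.trees) if rec.has_oob]
    if not usable:
        raise RuntimeError("every tree has an empty OOB set; cannot score features")

    X, y = _canonical(ensemble, data)
    deltas = np.zeros((len(usable), len(cols)))
    for row, tree_pos in enumerate(usable):
        acc = np.zeros(len(cols))
        for rep in range(n_permutations):
            acc += _tree_permuted_deltas(ensemble, X, y, tree_pos, cols, seed, rep)
        deltas[row] = acc / n_permutations

    return [
        summarize_deltas(str(f), deltas[:, j]) for j, f in enumerate(features)
    ]
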