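"""Bootstrap tree ensembles with per-tree out-of-bag bookkeeping.

Two base learners share one contract:

``random_bits_forest``
    A simplified random-bits-forest: a shared pool of randomised binary
    intermediate features ("bits", each a sparse thresholded linear
    combination of at most three raw features), a greedy boosting pass per
    tree that keeps the bits most predictive on that tree's bootstrap
    sample (within a random candidate subspace, for diversity), and a
    bagged forest of CART trees each trained on its own kept bits.

``plain_forest``
    A standard bagged forest of CART trees on the raw features with
    per-node random feature subsampling (the usual random-forest baseline).

Every tree records its bootstrap in-bag multiset, its out-of-bag (OOB)
sample set and its OOB accuracy; the OOB permutation importance in
``oob_importance`` consumes exactly this bookkeeping.

All randomness is derived from a single integer seed; fits are invariant
under reordering of the input rows because bootstrap draws and tree fits
operate in a canonical sample order (rows sorted by sample id).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .data_io import LabeledMatrix

_MAX_BIT_FEATURES = 3
_BIT_RETRIES = 10


def _norm_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def _rng(seed: int, *keys: int) -> np.random.Generator:
    """Child generator keyed on (seed, *keys); deterministic and independent."""
    return np.random.default_rng([_norm_seed(seed), *[int(k) for k in keys]])


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the bootstrap ensemble.

    ``n_trees`` is the ensemble size m over which per-tree accuracy drops are
    averaged; 200 keeps the importance variance estimate stable on
    tens-of-samples data. ``n_candidate_bits`` random bits are generated and
    ``n_selected_bits`` survive the boosting pass (random_bits_forest only).
    """

    n_trees: int = 200
    base_learner: Literal["random_bits_forest", "plain_forest"] = "random_bits_forest"
    n_candidate_bits: int = 1024
    n_selected_bits: int = 128
    max_tree_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.base_learner not in {"random_bits_forest", "plain_forest"}:
            raise ValueError(f"unknown base_learner {self.base_learner!r}")
        if self.n_selected_bits > self.n_candidate_bits:
            raise ValueError("n_selected_bits must be <= n_candidate_bits")


@dataclasses.dataclass
class TreeRecord:
    """Bootstrap bookkeeping for one tree (indices in canonical sample order)."""

    tree_index: int
    in_bag: np.ndarray  # multiset of canonical sample indices, length N
    oob: np.ndarray  # sorted canonical indices never drawn in-bag
    oob_accuracy: float | None  # None iff oob is empty

    @property
    def has_oob(self) -> bool:
        return self.oob.size > 0


class RandomBitLayer:
    """Randomised binary feature layer.

    Each bit thresholds a random sparse linear combination of at most three
    raw features at a random quantile of that combination's training-set
    distribution, so every bit splits the training data non-trivially.
    """

    def __init__(
        self,
        feature_idx: np.ndarray,  # (n_bits, 3) int, -1 padding
        weights: np.ndarray,  # (n_bits, 3) float, 0 padding
        thresholds: np.ndarray,  # (n_bits,)
    ) -> None:
        self.feature_idx = feature_idx
        self.weights = weights
        self.thresholds = thresholds

    @property
    def n_bits(self) -> int:
        return len(self.thresholds)

    def linear_scores(self, X: np.ndarray, bits: Sequence[int] | None = None) -> np.ndarray:
        """Pre-threshold scores, shape (n_samples, n_bits_requested)."""
        idx = self.feature_idx if bits is None else self.feature_idx[list(bits)]
        w = self.weights if bits is None else self.weights[list(bits)]
        # padding entries have weight 0; index -1 is harmless under that mask
        return np.einsum("sbf,bf->sb", X[:, idx], w)

    def transform(self, X: np.ndarray, bits: Sequence[int] | None = None) -> np.ndarray:
        thr = self.thresholds if bits is None else self.thresholds[list(bits)]
        return (self.linear_scores(X, bits) > thr).astype(np.float64)

    def bits_using_feature(self, feature: int, within: Sequence[int] | None = None) -> np.ndarray:
        """Indices (into ``within`` if given) of bits that read ``feature``."""
        idx = self.feature_idx if within is None else self.feature_idx[list(within)]
        return np.flatnonzero((idx == feature).any(axis=1))


@dataclasses.dataclass
class FittedEnsemble:
    """A fitted bootstrap ensemble plus everything importance needs."""

    trees: list[tuple[DecisionTreeClassifier, TreeRecord]]
    bit_layer: RandomBitLayer | None  # None for plain_forest
    selected_bits: np.ndarray | None  # (n_trees, n_selected) pool columns per tree
    classes: list
    config: EnsembleConfig
    sample_order: np.ndarray  # canonical order: argsort of training sample ids
    n_features_in: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def bootstrap_split(n_samples: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw one bootstrap sample of size ``n_samples`` with replacement.

    Returns the in-bag index multiset (length ``n_samples``) and the sorted
    out-of-bag complement. Roughly (1 - 1/N)^N ~ 36% of samples land out of
    bag for large N.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(seed)
    in_bag = rng.integers(0, n_samples, size=n_samples)
    oob = np.setdiff1d(np.arange(n_samples), in_bag)
    return in_bag, oob


def make_random_bits(
    X: np.ndarray, n_candidate_bits: int, seed: int
) -> RandomBitLayer:
    """Generate ``n_candidate_bits`` random threshold bits from training data.

    Each bit draws 1-3 distinct features, Gaussian weights, and a threshold
    at a uniform random quantile (20th-80th percentile) of the resulting
    linear score over the training rows. Features are dealt to bits from a
    shuffled round-robin over all columns, so the pool covers every feature
    at least once whenever it has enough slots (stratified rather than iid
    sampling; which features share a bit remains random). Bits whose score
    is constant on the training data are re-drawn a bounded number of
    times, then dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    n, p = X.shape
    rng = _rng(seed)

    # shuffled round-robin feature dealer: spreads slots evenly over columns
    k_max = min(_MAX_BIT_FEATURES, p)
    n_rounds = (n_candidate_bits * k_max) // p + 2
    deck = np.concatenate([rng.permutation(p) for _ in range(n_rounds)])
    deal_pos = 0

    feature_idx = np.full((n_candidate_bits, _MAX_BIT_FEATURES), -1, dtype=np.int64)
    weights = np.zeros((n_candidate_bits, _MAX_BIT_FEATURES))
    thresholds = np.empty(n_candidate_bits)
    keep = np.ones(n_candidate_bits, dtype=bool)

    for b in range(n_candidate_bits):
        for _ in range(_BIT_RETRIES):
            k = int(rng.integers(1, k_max + 1))
            feats = []
            while len(feats) < k:
                if deal_pos >= len(deck):  # exhausted after many retries
                    deck = np.concatenate([deck, rng.permutation(p)])
                cand = int(deck[deal_pos])
                deal_pos += 1
                if cand not in feats:
                    feats.append(cand)
            feats = np.asarray(feats, dtype=np.int64)
            w = rng.standard_normal(k)
            score = X[:, feats] @ w
            lo, hi = score.min(), score.max()
            if hi - lo <= 1e-12 * max(1.0, abs(hi)):
                continue  # constant combination (e.g. constant features)
            q = rng.uniform(0.2, 0.8)
            thr = float(np.quantile(score, q))
            if not (score > thr).any() or not (score <= thr).any():
                thr = float((lo + hi) / 2.0)
            feature_idx[b, :k] = feats
            weights[b, :k] = w
            thresholds[b] = thr
            break
        else:
            keep[b] = False
            warnings.warn(
                f"dropping bit {b}: no non-constant combination found",
                stacklevel=2,
            )

    return RandomBitLayer(feature_idx[keep], weights[keep], thresholds[keep])


def boost_select_bits(
    bits: np.ndarray, labels: np.ndarray, n_selected_bits: int
) -> list[int]:
    """Greedy forward selection of bits by boosted logistic loss reduction.

    Fits an additive model of one-bit stumps by gradient boosting with
    Newton leaf values: at each step every unselected bit's optimal stump is
    scored by its second-order loss reduction on the current margins, the
    best bit is added and the margins updated. Ties go to the lowest bit
    index; selection stops early if no bit reduces the loss. Deterministic.
    """
    B = np.asarray(bits, dtype=float)
    if B.ndim != 2 or B.shape[1] == 0:
        raise ValueError("bits must be a nonempty 2-D matrix")
    y = np.asarray(labels)
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("boost_select_bits requires >=2 classes")

    n, n_bits = B.shape
    if n_selected_bits >= n_bits:
        return list(range(n_bits))

    # one-vs-rest targets; binary problems reduce to a single column
    n_tasks = 1 if len(classes) == 2 else len(classes)
    Y = (
        (y_enc == 1).astype(float)[:, None]
        if n_tasks == 1
        else np.eye(len(classes))[y_enc]
    )
    F = np.zeros((n, n_tasks))
    lam = 1.0  # L2 on leaf values, keeps Newton steps bounded
    ones = B
    zeros = 1.0 - B

    selected: list[int] = []
    available = np.ones(n_bits, dtype=bool)
    for _ in range(n_selected_bits):
        prob = 1.0 / (1.0 + np.exp(-F))
        g = prob - Y  # (n, tasks)
        h = prob * (1.0 - prob)
        # per-bit leaf sums of gradients/hessians, all tasks at once
        G1 = ones.T @ g  # (n_bits, tasks)
        H1 = ones.T @ h
        G0 = zeros.T @ g
        H0 = zeros.T @ h
        gain = (G1**2 / (H1 + lam) + G0**2 / (H0 + lam)).sum(axis=1)
        gain[~available] = -np.inf
        best = int(np.argmax(gain))  # argmax takes the lowest index on ties
        if gain[best] <= 1e-12:
            break  # no informative bit left
        selected.append(best)
        available[best] = False
        leaf1 = -G1[best] / (H1[best] + lam)
        leaf0 = -G0[best] / (H0[best] + lam)
        F += np.where(B[:, best : best + 1] > 0.5, leaf1, leaf0)
    return selected


def _boost_select_bits_all_trees(
    all_bits: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    n_selected: int,
    allowed: np.ndarray,
) -> np.ndarray:
    """Per-tree greedy boosted bit selection, vectorised across trees.

    ``weights`` (n_samples, n_trees) are the bootstrap in-bag counts of each
    tree, so each tree's additive stump model is fit on its own bootstrap
    sample; ``allowed`` (n_bits, n_trees) masks each tree's candidate
    subspace. Same Newton-gain greedy rule as :func:`boost_select_bits`.
    Returns (n_trees, n_selected) pool column indices in selection order.
    """
    n, nb = all_bits.shape
    m = weights.shape[1]
    # float32 throughout: bit selection only needs the argmax of the gains,
    # which is insensitive to the last bits of precision
    B32 = np.asarray(all_bits, dtype=np.float32)
    W32 = np.asarray(weights, dtype=np.float32)
    Y = y[:, None].astype(np.float32)  # binary: P(class 1)
    F = np.zeros((n, m), dtype=np.float32)
    lam = np.float32(1.0)
    avail = allowed.copy()
    cols = np.arange(m)
    sel = np.empty((n_selected, m), dtype=np.int64)
    for s in range(n_selected):
        P = 1.0 / (1.0 + np.exp(-F))
        g = (P - Y) * W32
        h = P * (1.0 - P) * W32
        G1 = B32.T @ g  # (nb, m)
        H1 = B32.T @ h
        G0 = g.sum(axis=0)[None, :] - G1
        H0 = h.sum(axis=0)[None, :] - H1
        gain = G1**2 / (H1 + lam) + G0**2 / (H0 + lam)
        gain[~avail] = -np.inf
        best = gain.argmax(axis=0)  # lowest index on ties
        sel[s] = best
        avail[best, cols] = False
        leaf1 = -G1[best, cols] / (H1[best, cols] + lam)
        leaf0 = -G0[best, cols] / (H0[best, cols] + lam)
        F += np.where(B32[:, best] > 0.5, leaf1, leaf0)
    return sel.T


def fit_ensemble(data: LabeledMatrix, config: EnsembleConfig) -> FittedEnsemble:
    """Fit the bootstrap ensemble on a labeled matrix.

    Each tree is a CART classification tree (Gini impurity, no pruning)
    trained on its own bootstrap sample: for ``random_bits_forest`` on the
    ``n_selected_bits`` pool bits that boosting keeps for that tree (each
    tree boosts on its own bootstrap sample within a random half-pool-sized
    candidate subspace, so trees see diverse but informative bits); for
    ``plain_forest`` on raw features with per-node sqrt(p) subsampling.
    Trees whose bootstrap happens to cover every sample keep an empty OOB
    record (``oob_accuracy`` None) and are excluded from importance
    averaging downstream.
    """
    if data.n_classes() < 2:
        raise ValueError("fit_ensemble requires >=2 classes")
    if data.n_samples < 5:
        raise ValueError("fit_ensemble requires >=5 samples")

    order = np.argsort(data.sample_ids.astype(str), kind="stable")
    X = data.values[order]
    # class encoding follows first appearance in canonical row order, so the
    # whole fit is invariant to how the input rows happen to be arranged
    classes = list(dict.fromkeys(data.labels[order].tolist()))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.fromiter(
        (class_index[lab] for lab in data.labels[order]), dtype=np.int64,
        count=len(order),
    )
    n = X.shape[0]
    m = config.n_trees

    splits = [
        bootstrap_split(n, int(_rng(config.seed, 1, i).integers(2**31)))
        for i in range(m)
    ]

    bit_layer = None
    selected_bits = None
    if config.base_learner == "random_bits_forest":
        bit_layer = make_random_bits(X, config.n_candidate_bits, _norm_seed(config.seed))
        all_bits = bit_layer.transform(X)
        nb = bit_layer.n_bits
        k_sel = min(config.n_selected_bits, nb)
        if k_sel == nb:
            selected_bits = np.tile(np.arange(nb), (m, 1))
        else:
            weights = np.zeros((n, m))
            for i, (in_bag, _oob) in enumerate(splits):
                np.add.at(weights[:, i], in_bag, 1.0)
            subspace = min(nb, max(2 * k_sel, k_sel))
            allowed = np.zeros((nb, m), dtype=bool)
            for i in range(m):
                pick = _rng(config.seed, 4, i).choice(nb, size=subspace, replace=False)
                allowed[pick, i] = True
            if len(classes) == 2:
                selected_bits = _boost_select_bits_all_trees(
                    all_bits, y, weights, k_sel, allowed
                )
            else:  # multiclass fallback: per-tree greedy on in-bag rows
                selected_bits = np.empty((m, k_sel), dtype=np.int64)
                for i, (in_bag, _oob) in enumerate(splits):
                    sub = np.flatnonzero(allowed[:, i])
                    chosen = boost_select_bits(
                        all_bits[in_bag][:, sub], y[in_bag], k_sel
                    )
                    chosen = (
                        chosen + list(range(k_sel - len(chosen)))
                    )[:k_sel]  # pad deterministically if boosting stops early
                    selected_bits[i] = sub[np.asarray(chosen, dtype=np.int64)]
        max_features = None
    else:
        max_features = "sqrt"

    trees: list[tuple[DecisionTreeClassifier, TreeRecord]] = []
    for i in range(m):
        in_bag, oob = splits[i]
        R = all_bits[:, selected_bits[i]] if bit_layer is not None else X
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_depth=config.max_tree_depth,
            max_features=max_features,
            random_state=int(_rng(config.seed, 2, i).integers(2**31)),
        )
        tree.fit(R[in_bag], y[in_bag])
        if oob.size > 0:
            acc = float(np.mean(tree.predict(R[oob]) == y[oob]))
        else:
            acc = None
        trees.append((tree, TreeRecord(i, in_bag, oob, acc)))

    return FittedEnsemble(
        trees=trees,
        bit_layer=bit_layer,
        selected_bits=selected_bits,
        classes=classes,
        config=config,
        sample_order=order,
        n_features_in=data.n_features,
    )


def predict(ensemble: FittedEnsemble, X: np.ndarray) -> np.ndarray:
    """Majority-vote class prediction; ties go to the earlier-listed class."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ensemble.n_features_in:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"ensemble was fitted on {ensemble.n_features_in}"
        )
    all_bits = None
    if ensemble.bit_layer is not None:
        all_bits = ensemble.bit_layer.transform(X)
    votes = np.zeros((X.shape[0], len(ensemble.classes)), dtype=np.int64)
    for pos, (tree, _rec) in enumerate(ensemble.trees):
        R = X if all_bits is None else all_bits[:, ensemble.selected_bits[pos]]
        pred = tree.predict(R).astype(np.int64)
        votes[np.arange(X.shape[0]), pred] += 1
    winners = votes.argmax(axis=1)  # argmax -> first-listed class on ties
    return np.asarray([ensemble.classes[w] for w in winners], dtype=object)
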