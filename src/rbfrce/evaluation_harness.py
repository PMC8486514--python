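"""Repeated-holdout evaluation of feature-selection methods.

The protocol: split the data into a stratified 2/3 training / 1/3 test
holdout, run each selection method on the training split, refit the
ensemble on the selected top features and score it on the held-out third;
repeat (default 10 times) and average. The per-repeat rankings additionally
feed a stability-versus-k curve (mean pairwise sim_IM at each k in a grid),
which is how selection stability is compared across methods.

Methods available:

``rbf_rce``
    The full recursive-cluster-elimination selector.
``plain_forest_importance``
    Rank features by OOB permutation importance of a single plain random
    forest fit — the classic forest filter, used as the baseline.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .bit_ensemble import _rng, fit_ensemble, predict
from .data_io import LabeledMatrix
from .oob_importance import importance_scores
from .rce_selector import RCEConfig, run_rbf_rce
from .stability_metrics import stability_report

_SPLIT_RETRIES = 20


@dataclasses.dataclass(frozen=True)
class EvalConfig:
    n_repeats: int = 10
    train_fraction: float = 2.0 / 3.0
    k_grid: tuple[int, ...] = (5, 10, 20, 50)
    methods: tuple[str, ...] = ("rbf_rce", "plain_forest_importance")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if list(self.k_grid) != sorted(self.k_grid):
            raise ValueError("k_grid must be sorted ascending")
        bad = set(self.methods) - {"rbf_rce", "plain_forest_importance"}
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}")


@dataclasses.dataclass
class MethodResult:
    mean_accuracy: float
    per_repeat_accuracy: np.ndarray
    per_repeat_ranking: list[list[str]]
    stability_curve: dict[int, float]  # k -> mean pairwise sim_IM


@dataclasses.dataclass
class EvalResult:
    per_method: dict[str, MethodResult]
    config: EvalConfig


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test row indices, stratified by class.

    Each class contributes round(train_fraction * class size) training rows
    (at least one row on each side when the class has >=2 members).
    """
    labels = np.asarray(labels)
    rng = _rng(seed)
    train, test = [], []
    for cls in dict.fromkeys(labels.tolist()):  # first-appearance order
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_tr = int(round(train_fraction * len(idx)))
        if len(idx) >= 2:
            n_tr = min(max(n_tr, 1), len(idx) - 1)
        train.extend(idx[:n_tr].tolist())
        test.extend(idx[n_tr:].tolist())
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def _select_features(
    method: str, train: LabeledMatrix, rce_config: RCEConfig, seed: int
) -> list[str]:
    """Full feature ranking (best first) produced by one method."""
    if method == "rbf_rce":
        records, _state = run_rbf_rce(
            train, dataclasses.replace(rce_config, seed=seed)
        )
        return [r.feature_id for r in records]
    # plain_forest_importance: one forest fit, rank all features by fip
    ens_cfg = dataclasses.replace(
        rce_config.ensemble, base_learner="plain_forest", seed=seed
    )
    ens = fit_ensemble(train, ens_cfg)
    imps = importance_scores(ens, train, seed=seed)
    return [
        imp.feature_id
        for imp in sorted(imps, key=lambda im: (-im.fip, im.feature_id))
    ]


def run_evaluation(
    data: LabeledMatrix,
    config: EvalConfig,
    rce_config: RCEConfig | None = None,
) -> EvalResult:
    """Run the repeated-holdout protocol; deterministic given config.seed."""
    if rce_config is None:
        rce_config = RCEConfig()
    if data.n_samples < 9:
        raise ValueError("need at least 9 samples for a 2/3-1/3 holdout")

    n_classes = data.n_classes()
    per_method: dict[str, MethodResult] = {
        m: MethodResult(0.0, np.zeros(config.n_repeats), [], {})
        for m in config.methods
    }

    for rep in range(config.n_repeats):
        # stratified draw; re-drawn (bounded) if a class misses a side
        for attempt in range(_SPLIT_RETRIES):
            split_seed = int(_rng(config.seed, 20, rep, attempt).integers(2**31))
            tr_idx, te_idx = stratified_split(
                data.labels, config.train_fraction, split_seed
            )
            tr = data.subset_samples(tr_idx)
            te = data.subset_samples(te_idx)
            if tr.n_classes() == n_classes and te.n_classes() == n_classes:
                break
            warnings.warn(f"repeat {rep}: degenerate split, re-drawing", stacklevel=2)
        else:  # pragma: no cover - stratification makes this unreachable
            raise RuntimeError("could not draw a split covering every class")

        rep_seed = int(_rng(config.seed, 21, rep).integers(2**31))
        for method in config.methods:
            ranking = _select_features(method, tr, rce_config, rep_seed)
            top = ranking[: rce_config.target_features]
            refit_cfg = dataclasses.replace(rce_config.ensemble, seed=rep_seed)
            ens = fit_ensemble(tr.subset_features(top), refit_cfg)
            pred = predict(ens, te.subset_features(top).values)
            acc = float(np.mean(pred == te.labels))
            res = per_method[method]
            res.per_repeat_accuracy[rep] = acc
            res.per_repeat_ranking.append(ranking)

    for method, res in per_method.items():
        res.mean_accuracy = float(res.per_repeat_accuracy.mean())
        for k in config.k_grid:
            usable = min(k, min(len(r) for r in res.per_repeat_ranking))
            res.stability_curve[k] = stability_report(
                res.per_repeat_ranking, usable
            ).mean_sim

    return EvalResult(per_method=per_method, config=config)


def stability_curve_table(result: EvalResult) -> list[dict]:
    """Long-format rows (method, k, mean_sim) for CSV export/plotting."""
    rows = []
    for method, res in result.per_method.items():
        for k, sim in res.stability_curve.items():
            rows.append({"method": method, "k": k, "mean_sim": sim})
    return rows
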