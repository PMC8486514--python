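"""Top-k ranking stability: Fagin's intersection metric and selection priors.

Two ranked feature lists f_i, f_j of common length k are compared through
their prefixes: for each t = 1..k,

    delta_t = ( |f_i^t \\ f_j^t| + |f_j^t \\ f_i^t| ) / (2 t)

is the normalized symmetric difference of the top-t sets, and the
intersection metric IM(f_i, f_j) is the mean of delta_t over t. The
similarity sim_IM = 1 - IM lies in [0, 1]: 1 for identical rankings, 0 for
disjoint ones. Stability of a selection procedure is the mean pairwise
sim_IM over rankings obtained on perturbed training sets.

The module also provides the combinatorial priors that explain why
stability rises with k when selection were random: the chance that two
uniform random k-subsets of m features coincide (1 / C(m, k)) or share at
least one feature (1 - C(m-k, k) / C(m, k), monotone increasing in k).
"""

from __future__ import annotations

import dataclasses
from math import exp, lgamma
from typing import Sequence

import numpy as np


@dataclasses.dataclass(frozen=True)
class SelectionPriorParams:
    """m_total features in the pool, k selected."""

    m_total: int
    k: int

    def __post_init__(self) -> None:
        if self.m_total < 1:
            raise ValueError("m_total must be positive")
        if not 1 <= self.k <= self.m_total:
            raise ValueError(f"k={self.k} must lie in [1, m_total={self.m_total}]")


@dataclasses.dataclass
class StabilityReport:
    """Pairwise sim_IM of n_lists rankings truncated to their top k."""

    k: int
    pairwise_sim: np.ndarray  # (n_lists, n_lists), symmetric, unit diagonal
    mean_sim: float  # mean of the strict upper triangle
    n_lists: int


def _check_pair(f_i: Sequence[str], f_j: Sequence[str]) -> int:
    if len(set(f_i)) != len(f_i) or len(set(f_j)) != len(f_j):
        raise ValueError("ranked lists must not contain duplicates")
    if len(f_i) != len(f_j):
        raise ValueError(
            f"lists must have equal length (got {len(f_i)} and {len(f_j)}); "
            "truncate explicitly with truncate_rankings"
        )
    if len(f_i) < 1:
        raise ValueError("lists must be nonempty")
    return len(f_i)


def delta_t(f_i: Sequence[str], f_j: Sequence[str], t: int) -> float:
    """Normalized symmetric difference of the top-t prefix sets."""
    k = _check_pair(f_i, f_j)
    if not 1 <= t <= k:
        raise ValueError(f"t={t} out of range [1, {k}]")
    a, b = set(f_i[:t]), set(f_j[:t])
    return (len(a - b) + len(b - a)) / (2 * t)


def intersection_metric(f_i: Sequence[str], f_j: Sequence[str]) -> float:
    """IM(f_i, f_j) = mean over t = 1..k of delta_t; 0 iff identical lists."""
    k = _check_pair(f_i, f_j)
    a: set = set()
    b: set = set()
    inter = 0
    total = 0.0
    for t in range(1, k + 1):
        a.add(f_i[t - 1])
        b.add(f_j[t - 1])
        inter += (f_i[t - 1] in b) + (f_j[t - 1] in a) - (f_i[t - 1] == f_j[t - 1])
        # |sym diff| = 2t - 2|a & b|
        total += (t - inter) / t
    return total / k


def similarity_im(f_i: Sequence[str], f_j: Sequence[str]) -> float:
    """sim_IM = 1 - IM; 1 for identical rankings, 0 for disjoint ones."""
    return 1.0 - intersection_metric(f_i, f_j)


def truncate_rankings(
    rankings: Sequence[Sequence[str]], k: int
) -> list[list[str]]:
    """Explicitly truncate each ranking to its top-k items."""
    out = []
    for i, r in enumerate(rankings):
        if len(r) < k:
            raise ValueError(f"ranking {i} has only {len(r)} items, need {k}")
        out.append(list(r[:k]))
    return out


def stability_report(
    rankings: Sequence[Sequence[str]], k: int
) -> StabilityReport:
    """Mean pairwise sim_IM over the rankings' top-k prefixes."""
    if len(rankings) < 2:
        raise ValueError("need at least 2 rankings")
    tops = truncate_rankings(rankings, k)
    n = len(tops)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = similarity_im(tops[i], tops[j])
    iu = np.triu_indices(n, k=1)
    return StabilityReport(
        k=k, pairwise_sim=sim, mean_sim=float(sim[iu].mean()), n_lists=n
    )


def _log_comb(m: int, k: int) -> float:
    return lgamma(m + 1) - lgamma(k + 1) - lgamma(m - k + 1)


def prob_identical_subsets(params: SelectionPriorParams) -> float:
    """P(two independent uniform k-subsets of m coincide) = 1 / C(m, k)."""
    m, k = params.m_total, params.k
    return exp(-_log_comb(m, k))


def prob_share_feature(params: SelectionPriorParams) -> float:
    """P(two independent uniform k-subsets of m intersect).

    1 - C(m-k, k) / C(m, k); equals 1 by pigeonhole when 2k > m, and is
    monotone non-decreasing in k at fixed m.
    """
    m, k = params.m_total, params.k
    if 2 * k > m:
        return 1.0
    return 1.0 - exp(_log_comb(m - k, k) - _log_comb(m, k))


def brute_force_intersection_metric(
    f_i: Sequence[str], f_j: Sequence[str]
) -> float:
    """Literal prefix-set evaluation of IM, for cross-checking.

    Builds every top-t prefix set explicitly and averages the normalized
    symmetric differences; O(k^2), independent of the incremental
    implementation in :func:`intersection_metric`.
    """
    k = _check_pair(f_i, f_j)
    return sum(
        len(set(f_i[:t]) ^ set(f_j[:t])) / (2 * t) for t in range(1, k + 1)
    ) / k


def enumerate_prior_probabilities(m: int, k: int) -> tuple[float, float]:
    """Exhaustive-enumeration oracle for the selection priors (small m).

    Returns (P(identical), P(share at least one feature)) by iterating over
    all ordered pairs of k-subsets of range(m).
    """
    from itertools import combinations

    subsets = list(combinations(range(m), k))
    n = len(subsets)
    same = sum(1 for a in subsets for b in subsets if a == b)
    share = sum(1 for a in subsets for b in subsets if set(a) & set(b))
    return same / n**2, share / n**2


__all__ = [
    "SelectionPriorParams",
    "StabilityReport",
    "delta_t",
    "intersection_metric",
    "similarity_im",
    "truncate_rankings",
    "stability_report",
    "prob_identical_subsets",
    "prob_share_feature",
    "brute_force_intersection_metric",
    "enumerate_prior_probabilities",
]
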