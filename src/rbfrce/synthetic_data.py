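"""Synthetic high-dimensional small-sample datasets with planted structure.

Generates two-class expression-like matrices shaped like classic microarray
benchmarks (thousands of features, tens of samples): features are organised
into correlated blocks via a shared latent factor, and a small planted set of
informative features carries a class-conditional mean shift. The generator
returns the ground truth alongside the matrix so selection and stability
behaviour can be scored against known answers.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import LabeledMatrix


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    Defaults emulate a small two-class microarray study: 60 samples by 2000
    features with 20 informative genes spread over 50 correlated blocks.

    Attributes
    ----------
    n_samples, n_features
        Matrix shape (samples x features).
    n_informative
        Number of features carrying a class signal; distributed round-robin
        over the first blocks so signal sits inside correlated groups.
    n_blocks
        Number of correlated feature groups; features are assigned to blocks
        round-robin so block sizes differ by at most one.
    within_block_correlation
        Target pairwise Pearson correlation rho between features of one
        block, achieved by the factor model
        ``feature = sqrt(rho) * block_factor + sqrt(1 - rho) * noise``.
    effect_size
        Class-1 mean shift on informative features, in units of noise_sd.
    noise_sd
        Marginal standard deviation of every feature.
    class_balance
        P(class "1") for the Bernoulli label draw.
    seed
        Seed for all randomness; identical specs give bit-identical output.
    """

    n_samples: int = 60
    n_features: int = 2000
    n_informative: int = 20
    n_blocks: int = 50
    within_block_correlation: float = 0.6
    effect_size: float = 1.5
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_features < 1 or self.n_blocks < 1:
            raise ValueError("n_samples, n_features, n_blocks must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative={self.n_informative} must lie in "
                f"[0, n_features={self.n_features}]"
            )
        if not 0 <= self.within_block_correlation < 1:
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    informative_ids: frozenset
    block_assignment: dict


def make_dataset(spec: SyntheticSpec) -> tuple[LabeledMatrix, SyntheticTruth]:
    """Generate a labeled matrix plus ground truth from ``spec``.

    Labels are drawn first (Bernoulli ``class_balance``); class-1 samples get
    a mean shift of ``effect_size * noise_sd`` on every informative feature.
    Within a block, features share a latent Gaussian factor so their pairwise
    correlation is ``within_block_correlation`` in expectation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    rho = spec.within_block_correlation

    labels = (rng.random(n) < spec.class_balance).astype(int)

    block_of = np.arange(p) % spec.n_blocks  # round-robin assignment
    factors = rng.standard_normal((n, spec.n_blocks))
    idio = rng.standard_normal((n, p))
    values = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * idio
    values *= spec.noise_sd

    informative = np.arange(spec.n_informative)  # one per block, round-robin
    shift = spec.effect_size * spec.noise_sd
    values[np.ix_(labels == 1, informative)] += shift

    feature_ids = np.array([f"g{j:05d}" for j in range(p)], dtype=object)
    sample_ids = np.array([f"s{i:03d}" for i in range(n)], dtype=object)
    data = LabeledMatrix(
        values=values,
        labels=np.array(["c1" if y else "c0" for y in labels], dtype=object),
        feature_ids=feature_ids,
        sample_ids=sample_ids,
    )
    truth = SyntheticTruth(
        informative_ids=frozenset(feature_ids[informative].tolist()),
        block_assignment={fid: int(b) for fid, b in zip(feature_ids, block_of)},
    )
    return data, truth
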