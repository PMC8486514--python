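import numpy as np
import pytest

from rbfrce import EnsembleConfig, LabeledMatrix, SyntheticSpec, make_dataset


@pytest.fixture(scope="session")
def separable_toy() -> LabeledMatrix:
    """30 samples, 2 features, linearly separable classes."""
    rng = np.random.default_rng(42)
    n = 30
    y = np.repeat(["a", "b"], n // 2)
    x0 = np.where(y == "a", -2.0, 2.0) + 0.3 * rng.standard_normal(n)
    x1 = rng.standard_normal(n)
    return LabeledMatrix(
        values=np.column_stack([x0, x1]),
        labels=y,
        feature_ids=np.array(["signal", "noise"], dtype=object),
        sample_ids=np.array([f"s{i:02d}" for i in range(n)], dtype=object),
    )


@pytest.fixture(scope="session")
def small_planted():
    """60 x 200 synthetic dataset with 10 planted informative features."""
    spec = SyntheticSpec(
        n_samples=60, n_features=200, n_informative=10, n_blocks=20,
        effect_size=2.0, seed=11,
    )
    return make_dataset(spec)


@pytest.fixture(scope="session")
def fast_ensemble_config() -> EnsembleConfig:
    """Smaller ensemble for unit tests that only need the contract."""
    return EnsembleConfig(n_trees=60, n_candidate_bits=256, n_selected_bits=64, seed=5)
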