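import numpy as np
import pandas as pd
import pytest

from aiwrap import (
    CVConfig,
    Dataset,
    GAConfig,
    PipelineConfig,
    PPMConfig,
    get_scenario,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def fast_cv() -> CVConfig:
    return CVConfig(n_folds=5, seed=0, n_alphas=40)


@pytest.fixture(scope="session")
def tiny_ga() -> GAConfig:
    return GAConfig(pop_size=12, generations=8, seed=0)


@pytest.fixture(scope="session")
def fast_config(fast_cv, tiny_ga) -> PipelineConfig:
    """Desk-scale pipeline settings for tests that exercise the full stack."""
    return PipelineConfig(
        variant="L",
        ga=tiny_ga,
        ppm=PPMConfig(k_multiplier=8, n_trees=100),
        cv=fast_cv,
        b_importance=20,
        b_eval=15,
        threshold_ga=GAConfig(pop_size=8, generations=5),
        seed=0,
    )


@pytest.fixture(scope="session")
def interaction_data():
    """Train/test/targets for the small interaction scenario (p=15)."""
    return simulate_dataset(get_scenario("1_I", seed=7))


def make_dataset(X: np.ndarray, y: np.ndarray, names=None) -> Dataset:
    names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    return Dataset(X=pd.DataFrame(X, columns=names), y=pd.Series(y, name="y"))


@pytest.fixture(scope="session")
def signal_plus_noise():
    """n=80, y = 2*x1 + small noise, four pure-noise features."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((80, 5))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.1, 80)
    return make_dataset(X, y)
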