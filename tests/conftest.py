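import numpy as np
import pytest

from wtscausal import Dataset, RegressionSpec, gen_regression


@pytest.fixture(scope="session")
def planted_dataset() -> Dataset:
    """One strong planted linear predictor among independent noise features."""
    return gen_regression(
        RegressionSpec(
            n_samples=300,
            p_features=6,
            relevant_indices=(0,),
            effect_sizes=(2.0,),
            noise_sd=0.5,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def two_signal_dataset() -> Dataset:
    """Two planted predictors of different strength plus noise features."""
    return gen_regression(
        RegressionSpec(
            n_samples=250,
            p_features=7,
            relevant_indices=(0, 2),
            effect_sizes=(1.5, 0.8),
            noise_sd=0.6,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def tiny_dataset() -> Dataset:
    """Deterministic 6-sample table for exact hand calculations."""
    X = np.array(
        [
            [1.0, 2.0, 0.5],
            [2.0, 1.0, 1.5],
            [3.0, 4.0, 0.0],
            [4.0, 3.0, 2.0],
            [5.0, 6.0, 1.0],
            [6.0, 5.0, 2.5],
        ]
    )
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    return Dataset(X=X, y=y, feature_names=["a", "b", "c"])
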