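import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced trial (12 plots x 2 dates, 48 px) for fast module tests."""
    from maizelai import ExperimentDesign, generate_experiment

    design = ExperimentDesign(replicates=1, dates=2, image_size=48, seed=7)
    records, stacks = generate_experiment(design)
    return design, records, stacks


@pytest.fixture(scope="session")
def small_features(small_experiment):
    from maizelai import build_feature_table

    _, records, stacks = small_experiment
    return build_feature_table(records, stacks)


@pytest.fixture(scope="session")
def tabular_linear():
    """Noiseless linear regression problem for exact-fit limit checks."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + 0.7
    return X, y
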