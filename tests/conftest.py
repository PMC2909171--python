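import numpy as np
import pytest

from vacsmf import (
    CSMFVector,
    EstimatorConfig,
    SymptomDataset,
    SymptomModel,
    simulate_deaths,
)


@pytest.fixture
def tiny_hospital() -> SymptomDataset:
    """Four deaths, two causes, two symptoms: cause a -> {00, 01}, cause b -> {11, 11}."""
    return SymptomDataset(
        np.array([[0, 0], [0, 1], [1, 1], [1, 1]]),
        ["s1", "s2"],
        np.array([0, 0, 1, 1]),
        ["a", "b"],
    )


@pytest.fixture
def bernoulli_pair():
    """A moderately sized hospital/community pair drawn from one symptom model.

    Both samples share the same CSMF, so the estimator's target coincides
    with the hospital cause mix and estimates should recover it closely.
    """
    rng = np.random.default_rng(42)
    j, k = 5, 12
    p = rng.uniform(0.05, 0.9, size=(j, k))
    model = SymptomModel(
        p, [f"c{i}" for i in range(j)], [f"s{i + 1}" for i in range(k)]
    )
    csmf = CSMFVector(np.array([0.35, 0.25, 0.2, 0.12, 0.08]), model.cause_names)
    hospital = simulate_deaths(model, csmf, 2000, False, rng)
    community = simulate_deaths(model, csmf, 2000, False, rng).drop_cause_labels()
    return model, csmf, hospital, community


@pytest.fixture
def fast_config() -> EstimatorConfig:
    return EstimatorConfig(subset_size=6, n_subsets=60, seed=7)
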