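import numpy as np
import pytest

from autocmap import (
    AutoCMParams,
    default_study_spec,
    encode_cohort,
    link_strengths,
    simulate_cohort,
    train_autocm,
)
from autocmap.cohort import LatentStructure, MarginalSpec


@pytest.fixture(scope="session")
def study():
    specs, structure, schema = default_study_spec()
    return specs, structure, schema


@pytest.fixture(scope="session")
def cohort(study):
    specs, structure, _ = study
    return simulate_cohort(specs, structure, n=95, seed=7)


@pytest.fixture(scope="session")
def encoded(cohort):
    return encode_cohort(cohort)


@pytest.fixture(scope="session")
def trained(encoded):
    matrix, labels = encoded
    model = train_autocm(matrix, AutoCMParams())
    return model, labels


@pytest.fixture(scope="session")
def strengths(trained):
    model, labels = trained
    return link_strengths(model, labels=labels)


def planted_two_factor(loading: float = 0.7, per_factor: int = 6):
    """Compact two-factor study: per_factor Gaussians on each latent factor."""
    specs = []
    loadings = {}
    for i in range(per_factor):
        specs.append(MarginalSpec(f"M{i}", "truncated_gaussian", 0.0, 1.0, -6.0, 6.0))
        loadings[f"M{i}"] = {"f1": loading}
    for i in range(per_factor):
        specs.append(MarginalSpec(f"X{i}", "truncated_gaussian", 0.0, 1.0, -6.0, 6.0))
        loadings[f"X{i}"] = {"f2": loading}
    return specs, LatentStructure(("f1", "f2"), loadings)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
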