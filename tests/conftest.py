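import numpy as np
import pytest
from hypothesis import settings

from phyloherbivory import SimulationConfig, simulate_study
from phyloherbivory.glmm import FitOptions, build_model_data, fit_laplace

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: validated fast production settings (gradient-based outer optimisation);
#: agrees with the derivative-free default to ~1e-4 in all summaries
FAST_OPTS = FitOptions(outer_ftol=1e-7, restarts=0, outer_method="l-bfgs-b", outer_gtol=3e-4)


@pytest.fixture(scope="session")
def study():
    """One study-shaped synthetic dataset (38 plots, 27 modeled species)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_fit(study):
    data = build_model_data(study.plants, study.predictors)
    return fit_laplace(data, FAST_OPTS), data


@pytest.fixture(scope="session")
def small_study():
    """A small, quick-to-fit study for plumbing tests."""
    config = SimulationConfig(
        n_plots=10,
        n_species_pool=12,
        richness_range=(3, 7),
        n_phytometer=6,
        plants_per_species=2,
        leaf_poisson_mean=8.0,
        seed=7,
    )
    return simulate_study(config)


@pytest.fixture(scope="session")
def small_fit(small_study):
    data = build_model_data(small_study.plants, small_study.predictors)
    return fit_laplace(data, FAST_OPTS), data


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
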