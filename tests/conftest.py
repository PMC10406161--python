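import numpy as np
import pytest

import agealign as aa
from agealign.synthetic import EventTableSpec, gen_event_table


@pytest.fixture(scope="session")
def species_cfg():
    return aa.default_species_config()


@pytest.fixture(scope="session")
def study_table():
    """Default study-scale table: 9 species x 64 events, sigma=0.05, 30% missing."""
    return gen_event_table(EventTableSpec(seed=0))


@pytest.fixture(scope="session")
def fitted_study(study_table):
    """Imputed + scaled + fitted default bundle (table, scale, fit, truth)."""
    table, truth = study_table
    completed, _ = aa.impute_missing(table)
    scale = aa.compute_event_scale(completed)
    fit = aa.fit_translating_time(completed, scale)
    return completed, scale, fit, truth


@pytest.fixture(scope="session")
def affine_table():
    """Quadratic-free table (gamma=0): the event scale is exactly affine in
    the latent score, so fits and imputations have closed-form truth."""
    return gen_event_table(EventTableSpec(gamma=0.0, sigma=0.0, missing_frac=0.0, seed=1))


def two_species_warp_spec(alpha: float, seed: int = 0) -> EventTableSpec:
    """Two species whose log ages are related by log_age_B = alpha * log_age_A."""
    a, b = 4.0, 5.6
    return EventTableSpec(
        n_events=48,
        alpha={"human": a, "chimpanzee": alpha * a},
        beta={"human": b, "chimpanzee": alpha * b},
        gamma=0.0,
        sigma=0.01,
        missing_frac=0.0,
        n_event_types=1,
        seed=seed,
    )


@pytest.fixture(scope="session")
def warp_fit():
    """Fitted two-species model with a known log-scale warp of 1.15."""
    table, truth = gen_event_table(two_species_warp_spec(1.15))
    scale = aa.compute_event_scale(table)
    fit = aa.fit_translating_time(table, scale)
    return fit, 1.15


def rng_ages(n: int, seed: int = 0) -> np.ndarray:
    return np.exp(np.random.default_rng(seed).uniform(np.log(100), np.log(20000), n))
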