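import numpy as np
import pytest

from mrkit import SimConfig, cohort_to_summary, harmonize, simulate_cohort


@pytest.fixture(scope="session")
def cohort20():
    """Small default-condition cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_individuals=6000, n_variants=20, seed=42))


@pytest.fixture(scope="session")
def summary20(cohort20):
    return cohort_to_summary(cohort20)


@pytest.fixture(scope="session")
def iset20(cohort20, summary20):
    """Harmonized instrument set: published weights vs cohort outcome stats."""
    return harmonize(cohort20.variants, summary20[1])


@pytest.fixture(scope="session")
def cohort_null():
    """No causal effect, no pleiotropy, no confounding."""
    return simulate_cohort(
        SimConfig(
            n_individuals=10_000,
            n_variants=20,
            causal_beta=0.0,
            confounder_effect_exposure=0.0,
            confounder_effect_outcome=0.0,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
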