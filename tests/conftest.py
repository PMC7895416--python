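import pytest
from hypothesis import HealthCheck, settings

from obesity_sae import (
    GeoConfig,
    TruthConfig,
    apply_missingness,
    generate_geography,
    generate_population,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_geo():
    """60 block groups overlapping 25 zips, seeded."""
    return generate_geography(GeoConfig(n_blockgroups=60, n_zips=25, seed=101))


@pytest.fixture(scope="session")
def small_truth():
    return TruthConfig(n_individuals=4000, seed=102, intercept_similarity_corr=0.6)


@pytest.fixture(scope="session")
def small_cohort(small_geo, small_truth):
    """A 4,000-subject cohort with covariate-dependent missingness applied."""
    bg, ov = small_geo
    return apply_missingness(generate_population(bg, ov, small_truth), small_truth)
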