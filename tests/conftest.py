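import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldnb.synthetic_data import CohortSpec, fixture_small, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """The committed 10-molecule, 8-sample worked-example cohort."""
    return fixture_small()


@pytest.fixture(scope="session")
def reference_ids(small_cohort):
    return small_cohort.group_samples["control"]


@pytest.fixture(scope="session")
def strong_cohort():
    """One strong-effect synthetic cohort at the default study conditions."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def strong_results(strong_cohort):
    """Landscapes and global scores of the strong-effect cohort."""
    import warnings

    from ldnb.scoring import cohort_landscapes

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_landscapes(strong_cohort.abundance, strong_cohort.metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
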