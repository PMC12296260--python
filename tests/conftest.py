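import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def null_cohort():
    """Default-scale null cohort (delta = 0) used by several read-only tests."""
    from rdnat import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def window_cohort():
    """Five-month window cohort at the study's window size (n = 1200)."""
    from rdnat import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(months_range=(-5, 4), seed=11))
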