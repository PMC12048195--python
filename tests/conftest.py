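import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    from pahscreen.cohort import load_packaged_cohort

    return load_packaged_cohort()


@pytest.fixture(scope="session")
def design():
    """The shipped toy panel (reference + primers + pooled amplicons)."""
    from pahscreen.assay import build_toy_panel

    return build_toy_panel()


@pytest.fixture(scope="session")
def apv_table(cohort):
    from pahscreen.phenotyping import build_apv_table

    return build_apv_table(cohort)
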