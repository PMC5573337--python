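import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite",
        derandomize=True,
        max_examples=25,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass

from blmtu import reference_study, speciate


@pytest.fixture(scope="session")
def study_media():
    return reference_study.study_media()


@pytest.fixture(scope="session")
def study_specs(study_media):
    """Speciation of the twelve undosed study media (shared, read-only)."""
    return [speciate(m) for m in study_media]


@pytest.fixture(scope="session")
def cu_params():
    return reference_study.CU_PARAMS


@pytest.fixture(scope="session")
def co_params():
    return reference_study.CO_PARAMS


@pytest.fixture(scope="session")
def summaries():
    return reference_study.published_summaries()
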