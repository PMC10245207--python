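import pytest
from hypothesis import HealthCheck, settings

import noduletrade as nt

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_survey():
    """One seeded default survey (43 nests, 2150 nodules)."""
    return nt.simulate_survey(nt.default_config(seed=7))


@pytest.fixture(scope="session")
def default_traits(default_survey):
    return nt.nest_traits_table(
        default_survey.nodule_table, default_survey.nest_table
    )


@pytest.fixture()
def survey_csvs(tmp_path, default_survey):
    """The default survey written out as nodules.csv / nests.csv."""
    return default_survey.write_csvs(tmp_path)
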