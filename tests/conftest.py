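import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nhanes():
    """The packaged NHANES 2007-2008 infant cohort."""
    from pfascohort import load_nhanes_infants

    return load_nhanes_infants()


@pytest.fixture(scope="session")
def overrides():
    """Documented published-median overrides for the packaged cohort."""
    from pfascohort import nhanes_median_overrides

    return nhanes_median_overrides()


@pytest.fixture()
def small_panel():
    from pfascohort import AnalyteDef

    return [
        AnalyteDef("PFOA", "Perfluorooctanoic acid", 0.1),
        AnalyteDef("PFDA", "Perfluorodecanoic acid", 0.2),
        AnalyteDef("NOLOD", "analyte without a known LOD", None),
    ]


@pytest.fixture()
def small_table(small_panel):
    from pfascohort import CohortTable, SerumMeasurement

    records = [
        SerumMeasurement("s1", 0, "female", "PFOA", 3.5, False),
        SerumMeasurement("s2", 0, "male", "PFOA", 1.2, False),
        SerumMeasurement("s3", 1, "unknown", "PFOA", 2.2, False),
        SerumMeasurement("s1", 0, "female", "PFDA", 0.3, False),
        SerumMeasurement("s2", 0, "male", "PFDA", 0.14, True),
        SerumMeasurement("s3", 1, "unknown", "PFDA", 0.14, True),
        SerumMeasurement("s4", 1, "unknown", "PFDA", 0.14, True),
        SerumMeasurement("s5", 2, "unknown", "PFDA", 0.5, False),
    ]
    return CohortTable(panel=small_panel, records=records, provenance="unit-test table")
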