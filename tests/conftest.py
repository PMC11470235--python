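import pandas as pd
import pytest

import cohortgram as cgm


@pytest.fixture
def tiny_tables():
    """Three participants, Jan 1-10 2021, with serology and swab tables."""
    metadata = pd.DataFrame(
        {
            "participant_id": ["P01", "P02", "P03"],
            "group": ["long", "short", "long"],
            "dose_1_date": pd.to_datetime(["2021-01-02", "2021-01-03", pd.NaT]),
            "dose_2_date": pd.to_datetime(["2021-01-08", "2021-01-09", pd.NaT]),
        }
    )
    serology = pd.DataFrame(
        {
            "participant_id": ["P01", "P01", "P02"],
            "date": pd.to_datetime(["2021-01-02", "2021-01-09", "2021-01-05"]),
            "titer": [100.0, 400.0, 50.0],
        }
    )
    swab = pd.DataFrame(
        {
            "participant_id": ["P02", "P02"],
            "date": pd.to_datetime(["2021-01-04", "2021-01-06"]),
            "pcr": ["positive", "negative"],
        }
    )
    return metadata, serology, swab


@pytest.fixture
def tiny_cg(tiny_tables):
    metadata, serology, swab = tiny_tables
    return cgm.assemble(
        "2021-01-01",
        "2021-01-10",
        metadata,
        {"serology": serology, "swab": swab},
    )


@pytest.fixture(scope="session")
def small_cohort():
    return cgm.generate_cohort(cgm.CohortDesign(n_participants=40, seed=11))


@pytest.fixture(scope="session")
def small_cg(small_cohort):
    from helpers import assemble_cohort, full_annotate

    cg = assemble_cohort(small_cohort)
    return full_annotate(cg, small_cohort.design)
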