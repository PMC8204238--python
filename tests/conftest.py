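import numpy as np
import pandas as pd
import pytest

from cdmprivacy import generate_cdm, load_registry, presets


@pytest.fixture(scope="session")
def registry():
    return load_registry("synpuf5pct")


@pytest.fixture(scope="session")
def toy_cdm():
    """A small deterministic synthetic CDM shared across tests."""
    return generate_cdm(presets()["toy"].with_seed(11))


@pytest.fixture()
def micro_cdm():
    """A hand-written CDM fixture: 2 persons, 3 visits, known values,
    one condition row with a person lacking a location (null state)."""
    person = pd.DataFrame(
        {
            "person_id": [1, 2, 3],
            "year_of_birth": [1930, 1940, 1940],
            "month_of_birth": [3, 7, 7],
            "day_of_birth": [1, 1, 1],
            "gender_concept_id": [8507, 8532, 8532],
            "race_concept_id": [1, 1, 2],
            "ethnicity_concept_id": [38003564, 38003564, 38003563],
            "location_id": [10, 20, 99],  # 99 has no location row
        }
    )
    location = pd.DataFrame(
        {"location_id": [10, 20], "state": ["S01", "S02"], "county": ["C1", "C2"]}
    )
    provider = pd.DataFrame(
        {"provider_id": [100, 200], "npi": [111, 222], "care_site_id": [1, 1]}
    )
    care_site = pd.DataFrame(
        {"care_site_id": [1], "place_of_service_concept_id": [9202]}
    )
    visit = pd.DataFrame(
        {
            "visit_occurrence_id": [1000, 1001, 1002],
            "person_id": [1, 1, 2],
            "visit_start_date": pd.to_datetime(
                ["2008-01-05", "2009-06-01", "2010-12-31"]
            ),
            "visit_end_date": pd.to_datetime(
                ["2008-01-05", "2009-06-03", "2010-12-31"]
            ),
            "provider_id": [100, 200, 100],
            "care_site_id": [1, 1, 1],
        }
    )
    condition = pd.DataFrame(
        {
            "person_id": [1, 2, 3],
            "visit_occurrence_id": [1000, 1002, 1002],
            "condition_start_date": pd.to_datetime(
                ["2008-01-05", "2010-12-30", "2010-12-30"]
            ),
            "condition_end_date": pd.to_datetime(
                ["2008-01-06", "2010-12-31", "2010-12-31"]
            ),
            "condition_concept_id": [201826, 201826, 443767],
        }
    )
    death = pd.DataFrame(
        {"person_id": [2], "death_date": pd.to_datetime(["2010-12-31"])}
    )
    def empty_like(cols):
        def dtype_of(c):
            if c.endswith("_date"):
                return "datetime64[ns]"
            return "int64"
        return pd.DataFrame({c: pd.Series(dtype=dtype_of(c)) for c in cols})
    tables = {
        "person": person,
        "location": location,
        "provider": provider,
        "care_site": care_site,
        "visit_occurrence": visit,
        "condition_occurrence": condition,
        "death": death,
        "procedure_occurrence": empty_like(
            ["person_id", "visit_occurrence_id", "procedure_date", "procedure_concept_id"]
        ),
        "drug_exposure": empty_like(
            ["person_id", "visit_occurrence_id", "drug_exposure_start_date",
             "drug_exposure_end_date", "drug_concept_id"]
        ),
        "device_exposure": empty_like(
            ["person_id", "visit_occurrence_id", "device_exposure_start_date",
             "device_exposure_end_date", "device_concept_id"]
        ),
        "measurement": empty_like(
            ["person_id", "visit_occurrence_id", "measurement_date", "measurement_concept_id"]
        ),
        "observation": empty_like(
            ["person_id", "visit_occurrence_id", "observation_date", "observation_concept_id"]
        ),
    }
    from cdmprivacy import CdmTableSet

    return CdmTableSet(tables)


def pairwise_ec_histogram(frame: pd.DataFrame) -> dict[int, int]:
    """Independent O(N^2) equivalence-class oracle: build the full
    pairwise-equality matrix column by column and read class sizes off
    its row sums."""
    n = len(frame)
    if n == 0:
        return {}
    eq = np.ones((n, n), dtype=bool)
    for col in frame.columns:
        a = frame[col].to_numpy()
        eq &= np.equal(a[:, None], a[None, :])
    sizes = eq.sum(axis=1)  # size of the class each record belongs to
    hist = {}
    for k in np.unique(sizes):
        hist[int(k)] = int((sizes == k).sum() // k)
    return hist
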