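import numpy as np
import pandas as pd
import pytest

import spilldid as sd

# small but structurally complete study: 12 hospitals (4 treated),
# 3 physicians each, 2 specialties, 3 pre + 2 post quarters
TINY_OVERRIDES = {
    "n_hospitals": 12,
    "physicians_per_hospital": (3, 3),
    "specialties_per_hospital": 2,
    "quarters_pre": 3,
    "quarters_post": 2,
    "patients_per_physician_quarter": 10.0,
    "targeted_caseload_scale": 5.0,
}


@pytest.fixture(scope="session")
def tiny_config():
    return sd.build_scenario("combined", dict(TINY_OVERRIDES))


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return sd.simulate_study(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_timeline(tiny_study):
    return tiny_study.timeline


@pytest.fixture(scope="session")
def tiny_panel(tiny_study, tiny_config):
    catalogue = {c for c, _ in tiny_config.condition_catalogue}
    cohort, log = sd.build_cohort(
        tiny_study.admissions, tiny_study.deaths, tiny_study.timeline,
        catalogue=catalogue,
    )
    panel = sd.assemble_panel(cohort, tiny_study.hospitals, tiny_study.timeline)
    panel.attrs["exclusion_log"] = log.to_dict()
    return panel


@pytest.fixture(scope="session")
def tiny_exposure(tiny_study):
    return sd.compute_exposure_table(
        tiny_study.admissions, tiny_study.timeline, variants=True
    )


def make_admissions(rows: list[dict]) -> pd.DataFrame:
    """Toy admission table builder with schema-complete defaults."""
    defaults = {
        "patient_id": None,
        "hospital_id": "H0",
        "physician_id": "P0",
        "specialty_id": "S0",
        "quarter": 0,
        "admission_date": "2007-10-01",
        "emergency": True,
        "condition_code": "NT01",
        "diagnosis_area": "different_area",
        "targeted_primary": False,
        "targeted_secondary": False,
        "age_years": 70,
        "sex": "F",
        "deprivation_score": 0.0,
        "admitted_from_home": True,
        "via_ae": True,
        "weekend": False,
        "contracted_specialty": True,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["patient_id"] = f"PT{i:04d}"
        rec.update(row)
        out.append(rec)
    df = pd.DataFrame(out)
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    for j in range(1, 32):
        df[f"comorb_{j:02d}"] = False
    return df


def make_deaths(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["patient_id", "death_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
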