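import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gpcontinuity import CohortSpec, SyntheticConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def zeroed_config(**overrides) -> SyntheticConfig:
    """Generator config with every covariate effect switched off."""
    base = SyntheticConfig()
    kwargs = dict(
        ethnicity_concentration_effects={k: 0.0 for k in base.ethnicity_levels},
        age_effects={k: 0.0 for k in base.age_effects},
        sex_effects={"male": 0.0, "female": 0.0},
        deprivation_effect=0.0,
        practice_intercept_sd=0.0,
        consultation_age_rate_effects={k: 0.0 for k in base.age_effects},
        consultation_rate_per_ltc=0.0,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def _events(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "practice_id", "gp_id", "date", "mode"])


@pytest.fixture
def hand_fixture():
    """Seven hand-built patients exercising every eligibility rule.

    Expected outcome, derived by hand before implementation:

    * p1 — 10 visits (5 to g1, 1 each to g2–g6): eligible,
      UPC = 0.5, COC = (30−10)/90 = 2/9, follow-up 4.0 y,
      conditions asthma+depression → (2, "physical+mental").
    * p2 — 10 visits (5 to g1, 5 to g2): eligible, UPC = 0.5,
      COC = (50−10)/90 = 4/9, depression only → (1, "0-1").
    * p3 — 2 qualifying visits: excluded (fewer than minimum).
    * p4 — aged 17 at baseline, 10 visits: excluded on age.
    * p5 — exits 2016-06-01; 3 visits to g1 before exit, 2 after:
      eligible with UPC = COC = 1, follow-up 152/365.25 y.
    * p6 — 3 visits but missing ethnicity: excluded on covariates.
    * p7 — exited before baseline: excluded as not registered.
    """
    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(1, 8)],
            "practice_id": ["prac1"] * 7,
            "age_band": ["30-39", "40-49", "30-39", "<18", "80+", "50-59", "60-69"],
            "sex": ["female", "male", "male", "male", "female", "male", "female"],
            "ethnicity": ["White", "Bangladeshi", "White", "White", "Indian",
                          None, "White"],
            "imd_quintile": ["Q1", "Q5", "Q2", "Q3", "Q4", "Q1", "Q2"],
            "exit_date": [None, None, None, None, "2016-06-01", None, "2015-12-01"],
        }
    )
    rows = []
    for _ in range(5):
        rows.append(("p1", "prac1", "g1", "2016-02-01", "face_to_face"))
    for g in ("g2", "g3", "g4", "g5", "g6"):
        rows.append(("p1", "prac1", g, "2017-03-01", "telephone"))
    for g, n in (("g1", 5), ("g2", 5)):
        rows += [("p2", "prac1", g, "2018-05-05", "face_to_face")] * n
    rows += [("p3", "prac1", "g1", "2016-04-01", "face_to_face")] * 2
    rows += [("p4", "prac1", "g1", "2016-04-01", "face_to_face")] * 10
    rows += [("p5", "prac1", "g1", "2016-02-01", "online")] * 3
    rows += [("p5", "prac1", "g2", "2017-01-01", "face_to_face")] * 2  # after exit
    rows += [("p6", "prac1", "g2", "2016-07-01", "face_to_face")] * 3
    rows += [("p7", "prac1", "g1", "2016-02-01", "face_to_face")] * 5
    conditions = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2"],
            "condition": ["asthma", "depression", "depression"],
            "condition_class": ["physical", "mental", "mental"],
            "onset_date": ["2010-01-01", "2012-06-01", "2013-01-01"],
        }
    )
    return patients, _events(rows), conditions, CohortSpec()


@pytest.fixture(scope="session")
def age_bands():
    return ("18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
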