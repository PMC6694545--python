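import numpy as np
import pandas as pd
import pytest

from dynapred.cohort import Cohort, CohortConfig, generate_cohort
from dynapred.cox import CovariateSpec
from dynapred.landmark import LandmarkFrame


def make_frame(X, D, t0=0.0, horizon=None, **covariates):
    """Minimal landmark frame from raw arrays, numeric covariates only."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=int)
    data = {"id": np.arange(len(X)), "X": X, "D": D}
    for name, vals in covariates.items():
        data[name] = np.asarray(vals, dtype=float)
    if horizon is None:
        horizon = float(X.max())
    return LandmarkFrame(
        t0=float(t0),
        horizon=float(horizon),
        data=pd.DataFrame(data),
        excluded=pd.DataFrame(columns=["id", "reason"]),
        spec=CovariateSpec(numeric=tuple(covariates)),
    )


@pytest.fixture
def frame_factory():
    return make_frame


@pytest.fixture
def cox_fixture_frame():
    """Tiny tie-free frame with an interior partial-likelihood maximum."""
    return make_frame(
        X=[1.0, 2.0, 3.0, 4.0, 5.0],
        D=[1, 1, 0, 1, 0],
        z=[1.0, 2.0, 1.0, 0.0, 0.0],
    )


def make_toy_cohort():
    """Six subjects with labs at 0, 0.5, 1.0; two leave the risk set by t0=1."""
    subjects = pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4, 5],
            "arm": "placebo",
            "age_group": ["<40", "40-44", "<40", "65+", "50-54", "<40"],
            "gender": ["male", "female", "female", "male", "male", "female"],
            "bmi_group": ["<30", "35+", "30-35", "<30", "35+", "<30"],
            "smoking": ["no", "yes", "no", "no", "not_available", "no"],
            "race": ["white", "black", "white", "hispanic", "white", "other"],
            "X": [0.5, 1.0, 2.0, 3.0, 4.0, 5.0],
            "D": [1, 1, 1, 0, 1, 0],
        }
    )
    rows = []
    lab_values = {
        0: [(0.0, 100.0, 5.5), (0.5, 102.0, 5.6)],
        1: [(0.0, 110.0, 6.0), (0.5, 112.0, 6.1), (1.0, 115.0, 6.2)],
        2: [(0.0, 105.0, 5.8), (0.5, 106.0, 5.9), (1.0, 108.0, 6.0)],
        3: [(0.0, 95.0, 5.2), (0.5, 96.0, 5.3), (1.0, 97.0, 5.4)],
        # subject 4 misses the 1.0 visit labs: carry-forward from 0.5
        4: [(0.0, 120.0, 6.5), (0.5, 125.0, 6.7)],
        5: [(0.0, 101.0, 5.6), (0.5, 101.5, 5.65), (1.0, 103.0, 5.7)],
    }
    for sid, entries in lab_values.items():
        for t, g, h in entries:
            rows.append({"id": sid, "time_years": t,
                         "glucose_mgdl": g, "hba1c_pct": h})
    return Cohort(subjects, pd.DataFrame(rows), arm="placebo")


@pytest.fixture
def toy_cohort():
    return make_toy_cohort()


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate-size default-config cohort shared across tests."""
    return generate_cohort(CohortConfig(n_subjects=1200, seed=42))


@pytest.fixture(scope="session")
def default_cohort_pair():
    """Two-arm pair of small cohorts for study-level tests."""
    placebo = generate_cohort(CohortConfig(n_subjects=500, arm="placebo", seed=11))
    metformin = generate_cohort(
        CohortConfig(n_subjects=500, arm="metformin", seed=12)
    )
    return {"placebo": placebo, "metformin": metformin}
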