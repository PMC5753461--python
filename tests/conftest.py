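import numpy as np
import pandas as pd
import pytest

from hccscreen.cohort import preprocess
from hccscreen.peb import PEBParams
from hccscreen.simulate import SimConfig, generate_cohort

VA_PARAMS = PEBParams(theta_bar=2.92, sigma2=0.71, tau2=1.90)


@pytest.fixture(scope="session")
def va_params():
    """Hierarchical-model parameters of the VA control population."""
    return VA_PARAMS


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed synthetic cohort shared across tests."""
    cohort, truth = generate_cohort(SimConfig(n_controls=150, n_cases=40, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def small_screens(small_cohort):
    cohort, _ = small_cohort
    return preprocess(cohort)


@pytest.fixture()
def toy_cohort_frames():
    """Hand-sized cohort: 3 patients (1 case), enumerable by eye."""
    patients = pd.DataFrame(
        {
            "id": ["a", "b", "c"],
            "delta": [1, 0, 0],
            "d": [30.0, 60.0, 48.0],
            "baseline_age": [55.0, 50.0, 62.0],
        }
    )
    visits = pd.DataFrame(
        {
            "patient_id": ["a", "a", "a", "b", "b", "c"],
            "t": [6.0, 18.0, 27.0, 10.0, 30.0, 24.0],
            "afp": [8.0, 16.0, 120.0, 6.0, 7.0, 20.0],
        }
    )
    labs = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b", "c", "c"],
            "analyte": ["ALT", "PLT", "ALT", "ALT", "PLT"],
            "value": [60.0, 140.0, 45.0, 80.0, 90.0],
            "t": [5.0, 17.0, 9.0, 24.0, 20.0],
        }
    )
    return patients, visits, labs


def random_screens(rng: np.random.Generator, n_cases: int = 4, n_controls: int = 6) -> pd.DataFrame:
    """Random enumerable screen table with positivity, for oracle checks."""
    rows = []
    for i in range(n_cases + n_controls):
        delta = 1 if i < n_cases else 0
        d = rng.uniform(10, 60)
        for t in np.sort(rng.uniform(0, d, rng.integers(1, 6))):
            rows.append(
                {
                    "patient_id": f"p{i}",
                    "delta": delta,
                    "d": d,
                    "t": t,
                    "positive": bool(rng.random() < 0.3),
                    "score": rng.random(),
                    "afp": float(np.exp2(rng.normal(3, 1.6))),
                }
            )
    return pd.DataFrame(rows)
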