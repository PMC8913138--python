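import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from picurisk.cohort import COHORT_COLUMNS, Cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cohort(
    mid: np.ndarray,
    outcome: np.ndarray,
    pim2: np.ndarray | None = None,
    tiss28: np.ndarray | None = None,
    center: str = "oviedo",
    label: str = "test",
) -> Cohort:
    """Cohort with degenerate (point) trapezoids: MID is the only fuzzy info."""
    n = len(mid)
    mid = np.asarray(mid, dtype=float)
    frame = pd.DataFrame(
        {
            "patient_id": [f"p{i:05d}" for i in range(n)],
            "center": center,
            "outcome": np.asarray(outcome, dtype=int),
            "MID": mid,
            "SPR": 0.0,
            "SPRL": 0.0,
            "SPRR": 0.0,
            "PIM2": pim2 if pim2 is not None else np.zeros(n),
            "TISS28": tiss28 if tiss28 is not None else np.zeros(n),
        }
    )
    return Cohort(frame[list(COHORT_COLUMNS)], label=label)


@pytest.fixture
def tiny_patients_evals(tmp_path):
    """3-patient fixture with 1/2/3 evaluations plus one orphan patient."""
    patients = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "orphan"],
            "center": ["oviedo"] * 4,
            "outcome": [0, 0, 1, 0],
            "pim2": [1.0, 2.0, 40.0, 3.0],
            "tiss28": [10.0, 15.0, 30.0, 12.0],
        }
    )
    evals = pd.DataFrame(
        {
            "patient_id": ["a", "b", "b", "c", "c", "c"],
            "rater_role": ["physician", "nurse", "physician", "nurse", "nurse", "physician"],
            "short_lo": [20.0, 20.0, 40.0, 30.0, 50.0, 40.0],
            "short_hi": [40.0, 20.0, 40.0, 50.0, 90.0, 60.0],
            "long_lo": [10.0, 20.0, 40.0, 30.0, 40.0, 40.0],
            "long_hi": [70.0, 20.0, 40.0, 50.0, 90.0, 80.0],
        }
    )
    ppath = tmp_path / "patients.csv"
    epath = tmp_path / "evaluations.csv"
    patients.to_csv(ppath, index=False)
    evals.to_csv(epath, index=False)
    return ppath, epath
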