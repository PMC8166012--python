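import numpy as np
import pandas as pd
import pytest

from spotna24 import COHORT_COLUMNS


def make_record(**overrides) -> dict:
    """A plausible, fully populated participant record as a dict."""
    rec = {
        "id": "P0001", "sex": "F", "age_y": 49.0, "weight_kg": 66.6,
        "height_m": 1.58, "spot_na_mg_l": 2000.0, "spot_k_mmol_l": 37.0,
        "spot_cr_mg_dl": 96.0, "vol24_ml": 1500.0, "dur_h": 24.0,
        "missing_void": False, "na24_mg": 2700.0, "k24_mg": 1080.0,
        "cr24_g": 1.0, "pregnant": False, "fasting": False,
        "kidney_disease": False,
    }
    rec.update(overrides)
    return rec


def records_frame(*records) -> pd.DataFrame:
    """Assemble record dicts into a cohort DataFrame."""
    return pd.DataFrame(list(records), columns=COHORT_COLUMNS)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def small_cohort():
    """Ten handcrafted records, all passing default screening."""
    rows = []
    rng = np.random.default_rng(42)
    for i in range(10):
        rows.append(make_record(
            id=f"P{i + 1:04d}", sex="M" if i % 2 else "F",
            age_y=30.0 + 3 * i, weight_kg=55.0 + 2 * i,
            height_m=1.50 + 0.02 * i,
            spot_na_mg_l=1200.0 + 200 * i + float(rng.integers(0, 50)),
            spot_k_mmol_l=20.0 + 3 * i, spot_cr_mg_dl=60.0 + 8 * i,
            na24_mg=2000.0 + 150 * i,
        ))
    return records_frame(*rows)
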