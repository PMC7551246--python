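import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("reproducible", derandomize=True)
_hsettings.load_profile("reproducible")

from yyb_ecea import GrowthReference, SimConfig, generate_children, generate_provinces


@pytest.fixture(scope="session")
def growth_ref():
    return GrowthReference.bundled()


@pytest.fixture(scope="session")
def exact_ref():
    """Tiny reference with binary-exact arithmetic (median 75, sd 2.5)."""
    rows = [
        (sex, age, 75.0, 2.5)
        for sex in ("male", "female")
        for age in range(6, 37)
    ]
    return GrowthReference(pd.DataFrame(rows, columns=["sex", "age_months", "median_cm", "sd_cm"]))


@pytest.fixture(scope="session")
def small_world(growth_ref):
    """5 provinces x 200 children, default study conditions, seed 7."""
    cfg = SimConfig(n_provinces=5, children_per_province=200, seed=7)
    provinces = generate_provinces(cfg)
    children = generate_children(cfg, provinces, growth_ref)
    return cfg, provinces, children


def make_children(haz, ref, age=24, sex="male", province="P01", income=10.0,
                  t_hp=0.05, t_town=0.5):
    """Build a children table with prescribed HAZ values (single stratum)."""
    haz = np.asarray(haz, dtype=float)
    median, sd = ref.median_sd(sex, age)
    n = len(haz)
    return pd.DataFrame(
        {
            "child_id": [f"{province}-{i:05d}" for i in range(1, n + 1)],
            "province": province,
            "age_months": age,
            "sex": sex,
            "height_cm": median + haz * sd,
            "income_per_capita": income,
            "travel_time_health_post": t_hp,
            "travel_time_town": t_town,
            "survey_weight": 1.0,
        }
    )
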