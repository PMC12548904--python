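import numpy as np
import pandas as pd
import pytest

from taxdelay import generate_cohort
from taxdelay.hall import HallParameters


@pytest.fixture(scope="session")
def hall_params() -> HallParameters:
    return HallParameters()


@pytest.fixture(scope="session")
def person() -> dict:
    """A reference middle-aged woman with class-1 obesity."""
    return {"age": 50, "sex": "female", "height": 160.0, "weight": 76.8,
            "pal": 1.55}


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return generate_cohort(300, seed=42)


@pytest.fixture(scope="session")
def flat_multipliers() -> dict:
    return {y: 1.0 for y in range(2021, 2041)}
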