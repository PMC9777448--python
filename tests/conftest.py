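import numpy as np
import pandas as pd
import pytest

from epiclock import (
    CohortSpec,
    GroupSpec,
    MethylationMatrix,
    SampleSheet,
    UnitModel,
    simulate_targeted_cohort,
)


@pytest.fixture(scope="session")
def small_units():
    """Twelve CpG-unit models in two amplicons, mixed slope signs."""
    rng = np.random.default_rng(42)
    units = []
    for region, n in [("ampA", 7), ("ampB", 5)]:
        for k in range(1, n + 1):
            slope = rng.choice([-1, 1]) * rng.uniform(0.01, 0.04)
            base = rng.uniform(0.25, 0.75)
            units.append(
                UnitModel(
                    unit_id=f"{region}_unit{k}",
                    slope_m=float(slope),
                    intercept_m=float(np.log2(base / (1 - base)) - slope * 50),
                    sd_unit=0.12,
                    region_id=region,
                )
            )
    return units


@pytest.fixture(scope="session")
def small_cohort(small_units):
    """Sixty controls aged 21-80 with 5% missingness."""
    spec = CohortSpec(
        groups=(GroupSpec("CTR", n=60, age_low=21, age_high=80, sd_accel=3.0),),
        missing_rate=0.05,
        seed=7,
    )
    return simulate_targeted_cohort(small_units, spec)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 units with one missing entry."""
    df = pd.DataFrame(
        {"u1": [0.1, 0.5, 0.9], "u2": [0.2, np.nan, 0.8]},
        index=["s1", "s2", "s3"],
    )
    return MethylationMatrix(df)


@pytest.fixture
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "age": [21, 40, 60, 80],
                "sex": ["F", "M", "F", "M"],
                "group": ["CTR", "CTR", "CTR", "CTR"],
            }
        )
    )
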