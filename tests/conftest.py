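import numpy as np
import pandas as pd
import pytest

from sheeppool.synthetic_data import (
    generate_population,
    tan_sheep_population_spec,
)

# the published per-breed genotype counts (n_II, n_ID, n_DD) and cohort sizes
TABLE1_COUNTS = {
    "TS": (894, 13, 0),
    "LXBH": (615, 14, 0),
    "STHS": (187, 3, 0),
    "LFTS": (48, 1, 0),
    "HS": (201, 0, 0),
    "SS": (48, 0, 0),
    "AUW": (326, 0, 0),
}


@pytest.fixture(scope="session")
def seven_breed_population() -> pd.DataFrame:
    return generate_population(tan_sheep_population_spec(seed=20200821))


@pytest.fixture(scope="session")
def table1_records() -> pd.DataFrame:
    """Genotype records reconstructed exactly from the published counts."""
    rows = []
    for breed, (n_ii, n_id, n_dd) in TABLE1_COUNTS.items():
        for code, count in zip((0, 1, 2), (n_ii, n_id, n_dd)):
            for k in range(count):
                rows.append(
                    {
                        "id": f"{breed}_{code}_{k}",
                        "breed": breed,
                        "sex": "unknown",
                        "genotype": code,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
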